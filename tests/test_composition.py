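import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import magdecon as m
from magdecon.composition import nb_scores_batch


def kmer_dict(counts, k=4):
    """Decode a count vector into {motif: count} for readable asserts."""
    bases = "ACGT"
    out = {}
    for code, c in enumerate(counts):
        if c:
            motif = "".join(bases[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))
            out[motif] = int(c)
    return out


class TestCountKmers:
    def test_hand_enumeration(self):
        counts = m.count_kmers("ACGTACGT", 4, "forward")
        assert kmer_dict(counts) == {"ACGT": 2, "CGTA": 1, "GTAC": 1, "TACG": 1}
        assert counts.sum() == 5

    def test_single_window(self):
        assert kmer_dict(m.count_kmers("AAAA", 4)) == {"AAAA": 1}

    def test_every_window_spans_n(self):
        assert m.count_kmers("ACNGT", 4).sum() == 0

    def test_k_longer_than_sequence(self):
        assert m.count_kmers("ACG", 4).sum() == 0

    def test_both_strands_adds_revcomp(self):
        fwd = m.count_kmers("ACGTACGT", 4, "forward")
        both = m.count_kmers("ACGTACGT", 4, "both")
        assert both.sum() == 2 * fwd.sum()

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=200),
           st.integers(min_value=1, max_value=6))
    def test_sum_rule(self, seq, k):
        assert m.count_kmers(seq, k, "forward").sum() == max(0, len(seq) - k + 1)


class TestTetra:
    def test_null_mean_abs_z(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), 50_000))
        mean_abs = np.abs(m.tetra_zscores(seq).z).mean()
        assert 0.5 <= mean_abs <= 1.1  # half-normal mean ~0.80 under the null

    def test_homopolymer_degenerates_to_zero(self):
        assert np.all(m.tetra_zscores("A" * 10_000).z == 0)

    def test_duplication_stability(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 20_000))
        a = m.tetra_zscores(seq)
        b = m.tetra_zscores(seq + seq)
        assert np.corrcoef(a.z, b.z)[0, 1] >= 0.99

    def test_below_floor_errors(self):
        with pytest.raises(ValueError, match="concatenat"):
            m.tetra_zscores("ACGT" * 100)

    def test_correlation_identities(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 30_000))
        sig = m.tetra_zscores(seq)
        neg = m.TetraSignature(-sig.z)
        assert m.tetra_correlation(sig, sig) == pytest.approx(1.0)
        assert m.tetra_correlation(sig, neg) == pytest.approx(-1.0)

    def test_correlation_symmetric_and_null(self):
        rng = np.random.default_rng(6)
        a = m.tetra_zscores("".join(rng.choice(list("ACGT"), 50_000)))
        b = m.tetra_zscores("".join(rng.choice(list("ACGT"), 50_000)))
        assert m.tetra_correlation(a, b) == m.tetra_correlation(b, a)
        assert abs(m.tetra_correlation(a, b)) < 0.3

    def test_constant_signature_flagged_zero(self):
        const = m.TetraSignature(np.zeros(256))
        rng = np.random.default_rng(6)
        other = m.tetra_zscores("".join(rng.choice(list("ACGT"), 30_000)))
        assert m.tetra_correlation(const, other) == 0.0


class TestNaiveBayes:
    def test_training_limit_cases(self):
        model = m.train_nb_model(["A" * 20_000], "a", pseudocount=1e-9)
        ctx_aaa = 0  # context AAA
        assert np.exp(model.cond_logp[ctx_aaa, 0]) == pytest.approx(1.0, abs=1e-6)
        uniform = m.train_nb_model(["A" * 20_000], "u", pseudocount=1.0)
        # an unobserved context falls back to the pseudocount-uniform distribution
        assert np.allclose(np.exp(uniform.cond_logp[17]), 0.25)

    def test_training_deterministic(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), 20_000))
        a = m.train_nb_model([seq], "x")
        b = m.train_nb_model([seq], "x")
        assert np.array_equal(a.cond_logp, b.cond_logp)

    def test_empty_or_small_training_rejected(self):
        with pytest.raises(ValueError):
            m.train_nb_model([], "x")
        with pytest.raises(ValueError, match="floor"):
            m.train_nb_model(["ACGT" * 100], "x")

    def test_uniform_model_closed_form(self):
        uniform = m.MotifModel("u", np.full((64, 4), np.log(0.25)), 1.0, 0)
        L = 137
        seq = "ACGT" * 34 + "A"
        assert m.nb_log_posterior(uniform, seq) == pytest.approx((L - 3) * np.log(0.25))
        assert m.nb_log_posterior(uniform, seq, prior=0.5) == pytest.approx(
            (L - 3) * np.log(0.25) + np.log(0.5))

    def test_additivity_over_concatenation(self, markov_pair):
        _, models = markov_pair
        model = models["A"]
        rng = np.random.default_rng(9)
        x = "".join(rng.choice(list("ACGT"), 500))
        y = "".join(rng.choice(list("ACGT"), 500))
        whole = m.nb_log_posterior(model, x + y)
        # boundary windows: the 3 windows whose context straddles the joint
        boundary = sum(
            model.cond_logp.reshape(256)[
                m.composition._window_codes(m.composition.encode_sequence(
                    (x + y)[len(x) - 3 + i: len(x) + 1 + i]), 4)[0][0]]
            for i in range(3))
        parts = m.nb_log_posterior(model, x) + m.nb_log_posterior(model, y)
        assert whole == pytest.approx(parts + boundary, rel=1e-12)

    def test_short_or_all_n_rejected(self, markov_pair):
        _, models = markov_pair
        with pytest.raises(ValueError):
            m.nb_log_posterior(models["A"], "ACG")
        with pytest.raises(ValueError):
            m.nb_log_posterior(models["A"], "N" * 50)

    def test_single_model_classification_rejected(self, markov_pair):
        _, models = markov_pair
        with pytest.raises(ValueError):
            m.nb_classify([models["A"]], "ACGTACGT")

    def test_tie_broken_lexicographically(self, markov_pair):
        _, models = markov_pair
        twin = m.MotifModel("zz_twin", models["A"].cond_logp, 1.0, 0)
        res = m.nb_classify([twin, models["A"]], "ACGTACGTACGT")
        assert res.best_label == "A" and res.tie and res.margin == 0.0

    def test_self_classification_accuracy_and_monotonicity(self, markov_pair):
        """>=95% of 5-kb fragments classify to their source genome, and
        accuracy is non-decreasing in fragment length (one <=1% inversion
        allowed)."""
        genomes, models = markov_pair
        model_list = [models["A"], models["B"]]
        rng = np.random.default_rng(10)
        accs = []
        for frag_len in (1_000, 2_000, 5_000, 10_000):
            correct = total = 0
            for lab, g in genomes.items():
                starts = rng.integers(0, len(g) - frag_len, size=100)
                frags = [g[s : s + frag_len] for s in starts]
                scores = nb_scores_batch(model_list, frags)
                pred = np.argmax(scores, axis=1)
                correct += int((pred == (0 if lab == "A" else 1)).sum())
                total += len(frags)
            accs.append(100.0 * correct / total)
        assert accs[2] >= 95.0
        inversions = [max(0.0, accs[i] - accs[i + 1]) for i in range(3)]
        assert sum(1 for d in inversions if d > 0) <= 1
        assert all(d <= 1.0 for d in inversions)

    def test_batch_scores_match_single(self, markov_pair):
        genomes, models = markov_pair
        frag = genomes["A"][1000:3000]
        batch = nb_scores_batch([models["A"], models["B"]], [frag])
        assert batch[0, 0] == pytest.approx(m.nb_log_posterior(models["A"], frag))
        assert batch[0, 1] == pytest.approx(m.nb_log_posterior(models["B"], frag))


def test_model_and_signature_json_round_trip(markov_pair):
    from magdecon.composition import (model_from_json, model_to_json,
                                      signature_from_json, signature_to_json)
    _, models = markov_pair
    back = model_from_json(model_to_json(models["A"]))
    assert back.label == "A" and np.array_equal(back.cond_logp, models["A"].cond_logp)
    rng = np.random.default_rng(14)
    sig = m.tetra_zscores("".join(rng.choice(list("ACGT"), 20_000)))
    assert np.array_equal(signature_from_json(signature_to_json(sig)).z, sig.z)
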