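import numpy as np
import pytest

import magdecon as m
from magdecon.alignment_af import AFRecord
from magdecon.coverage import CoverageRange, CoverageSummary
from magdecon.deconvolve import split_scores_at_cutoff


def af(scaf, iso, pct):
    return AFRecord(scaf, iso, pct, int(pct * 10), 1000)


class TestStep2:
    def test_single_high_af(self):
        asn, conflicts, deferred = m.step2_assign_isolates([af("s1", "iso1", 99.5)])
        assert asn["s1"].label == "iso1" and asn["s1"].step_tag == "step2"
        assert not conflicts and not deferred

    def test_conflict_resolved_by_max_af(self):
        asn, conflicts, _ = m.step2_assign_isolates(
            [af("s2", "iso1", 95.0), af("s2", "iso2", 92.0)])
        assert asn["s2"].label == "iso1" and len(conflicts) == 1

    def test_boundary_deferred(self):
        asn, _, deferred = m.step2_assign_isolates([af("s3", "iso1", 89.9)])
        assert "s3" not in asn and deferred == {"s3"}

    def test_idempotent(self):
        recs = [af("s1", "iso1", 99.0), af("s2", "iso2", 91.0)]
        once, _, _ = m.step2_assign_isolates(recs)
        again, _, _ = m.step2_assign_isolates(recs)
        assert once == again


class TestStep3:
    ranges = {"A": CoverageRange("A", 35, 45), "B": CoverageRange("B", 18, 23)}

    def summ(self, depths):
        return {s: CoverageSummary(s, d, 5000, True) for s, d in depths.items()}

    def test_unique_range_assigned(self):
        asn, deferred, pending = m.step3_assign_unaligned(
            ["u1"], self.summ({"u1": 40.0}), self.ranges, None, {})
        assert asn["u1"].label == "A" and asn["u1"].step_tag == "step3_unique"

    def test_outside_all_ranges_deferred(self):
        asn, deferred, _ = m.step3_assign_unaligned(
            ["u2"], self.summ({"u2": 70.0}), self.ranges, None, {})
        assert deferred == {"u2"}

    def test_ambiguous_resolved_by_restricted_nb(self, markov_pair):
        genomes, models = markov_pair
        ranges = {"A": CoverageRange("A", 20, 25), "B": CoverageRange("B", 22, 30)}
        seq = genomes["B"][0:4000]
        asn, _, _ = m.step3_assign_unaligned(
            ["u3"], self.summ({"u3": 23.0}), ranges, models, {"u3": seq})
        assert asn["u3"].label == "B" and asn["u3"].step_tag == "step3_nb"

    def test_missing_coverage_errors(self):
        with pytest.raises(ValueError, match="u9"):
            m.step3_assign_unaligned(["u9"], {}, self.ranges, None, {})


class TestStep4:
    def test_unique_range_wins(self, markov_pair):
        _, models = markov_pair
        ranges = {"A": CoverageRange("A", 35, 45)}
        summ = {"d1": CoverageSummary("d1", 40.0, 5000, True)}
        asn = m.step4_assign_low_af(["d1"], [], summ, ranges, models, set(), {})
        assert asn["d1"].label == "A" and asn["d1"].step_tag == "step4_unique"

    def test_isolate_needs_alignment(self, markov_pair):
        genomes, models = markov_pair
        seq = genomes["A"][0:4000]
        summ = {"d2": CoverageSummary("d2", 999.0, 4000, True)}
        ranges = {"A": CoverageRange("A", 1, 2)}  # depth matches nothing
        # with an alignment on the scaffold the isolate takes it
        asn = m.step4_assign_low_af(
            ["d2"], [af("d2", "A", 45.0)], summ, ranges, models, {"A"}, {"d2": seq})
        assert asn["d2"].label == "A" and asn["d2"].step_tag == "step4_nb_isolate"
        # without one the scaffold must go to the best uncultured component
        asn2 = m.step4_assign_low_af(
            ["d2"], [], summ, ranges, models, {"A"}, {"d2": seq})
        assert asn2["d2"].label == "B" and asn2["d2"].step_tag == "step4_nb_uncultured"


class TestStep5Cutoff:
    scores = {"a": -1200.0, "b": -1220.0, "c": -1480.0, "d": -1500.0}

    def test_auto_matches_explicit_minus_1350(self):
        hi, lo, cut = split_scores_at_cutoff(self.scores, "auto")
        assert hi == {"a", "b"} and lo == {"c", "d"}
        hi2, lo2, _ = split_scores_at_cutoff(self.scores, -1350.0)
        assert (hi2, lo2) == (hi, lo)

    def test_unimodal_scores_refused(self):
        rng = np.random.default_rng(11)
        scores = {f"s{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 60))}
        with pytest.raises(ValueError, match="bimodal"):
            split_scores_at_cutoff(scores, "auto")

    def test_one_sided_cutoff_refused(self):
        with pytest.raises(ValueError, match="empty"):
            split_scores_at_cutoff(self.scores, -2000.0)


class TestStep5Split:
    def test_synthetic_merged_pair_split_accuracy(self, truth, tabular, pipeline_result):
        """>=90% of the merged pair's scaffolds return to their true genome
        after the SCG-duplicate-seeded split."""
        gold = tabular["gold"]
        pair = {truth.genome_labels[i] for i in truth.config.overlap_pair}
        bins = {s: a.label for s, a in pipeline_result.assignments.items()}
        members = [s for s, g in gold.items() if g in pair and s in bins]
        split_bins = {b for s, b in bins.items() if s in members}
        assert len(split_bins) == 2, "merged bin was not split in two"
        # accuracy under the best bin<->genome matching
        from collections import Counter
        counts = Counter((gold[s], bins[s]) for s in members)
        b1, b2 = sorted(split_bins)
        g1, g2 = sorted(pair)
        acc1 = counts[(g1, b1)] + counts[(g2, b2)]
        acc2 = counts[(g1, b2)] + counts[(g2, b1)]
        assert max(acc1, acc2) / len(members) >= 0.90

    def test_seed_group_validation(self, markov_pair):
        genomes, models = markov_pair
        rng = np.random.default_rng(12)
        recs = []
        for lab, g in genomes.items():
            for i in range(10):
                s = int(rng.integers(0, len(g) - 8000))
                recs.append(m.ScaffoldRecord(f"{lab}{i}", g[s : s + 8000]))
        dup = {r.id for r in recs}
        external = m.train_nb_model(["".join(rng.choice(list("ACGT"), 60_000))], "ext")
        sides, cut, seeds = m.step5_split_merged_bin(recs, dup, external)
        by_side = {}
        for r in recs:
            by_side.setdefault(sides[r.id], set()).add(r.id[0])
        # each side should be pure in source genome
        assert all(len(v) == 1 for v in by_side.values())

    def test_dup_scaffolds_must_belong(self, markov_pair):
        genomes, _ = markov_pair
        recs = [m.ScaffoldRecord("x", genomes["A"][:8000])]
        ext = m.train_nb_model([genomes["B"]], "ext")
        with pytest.raises(ValueError):
            m.step5_split_merged_bin(recs, {"x", "ghost"}, ext)


class TestRunPipeline:
    def test_totality_and_determinism(self, truth, depth_table, tabular, summaries,
                                      pipeline_result):
        res = pipeline_result
        assert set(res.assignments) | set(res.excluded_short) == {r.id for r in truth.scaffolds}
        assert not res.excluded_short  # generator never emits < 500 bp
        cfg = m.PipelineConfig(ranges=m.component_range_plan(truth, summaries))
        rerun = m.run_pipeline(truth.scaffolds, tabular["hits"], depth_table,
                               tabular["scg_hits"], cfg)
        assert {s: (a.label, a.step_tag) for s, a in rerun.assignments.items()} == \
               {s: (a.label, a.step_tag) for s, a in res.assignments.items()}

    def test_bp_accounting_conservation(self, truth, pipeline_result):
        lengths = truth.scaffold_lengths()
        per_step = pipeline_result.report["per_step"]
        assert sum(v["bp"] for v in per_step.values()) == pipeline_result.report["assigned_bp"]
        assert sum(v["n"] for v in per_step.values()) == len(pipeline_result.assignments)

    def test_missing_depth_errors(self, truth, tabular):
        cfg = m.PipelineConfig(ranges={"X": CoverageRange("X", 1, 2)})
        with pytest.raises(ValueError, match="depth"):
            m.run_pipeline(truth.scaffolds[:5], tabular["hits"][:0], {}, [], cfg)

    def test_empty_scaffolds_rejected(self):
        with pytest.raises(ValueError):
            m.run_pipeline([], [], {}, [], m.PipelineConfig())

    def test_step_tags_within_contract(self, pipeline_result):
        from magdecon.deconvolve import STEP_TAGS
        assert {a.step_tag for a in pipeline_result.assignments.values()} <= set(STEP_TAGS)
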