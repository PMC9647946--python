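"""Tetranucleotide composition statistics and the 4-nt-motif naive Bayesian
classifier.

Two composition signals drive the pipeline:

* **TETRA z-scores** — for each of the 256 tetranucleotides, the deviation of
  its observed count from the expectation under a maximal-order Markov model
  built from the sequence's own trinucleotide and dinucleotide counts::

      E(n1n2n3n4)   = N(n1n2n3) * N(n2n3n4) / N(n2n3)
      Var(n1n2n3n4) = E * (N(n1n2n3) - N(n2n3)) * (N(n2n3n4) - N(n2n3)) / N(n2n3)^2
      z             = (O - E) / sqrt(Var)

  Two sequences are compared by the Pearson correlation of their z-vectors
  (the "TETRA value"). Counting is over both strands (each motif plus its
  reverse complement), the convention of the TETRA literature.

* **Naive Bayes (order-3 Markov) models** — per component, the conditional
  probability of each base given its preceding trinucleotide, estimated from
  training sequence with a Laplace pseudocount. A sequence's log posterior
  under a model is the sum of log conditionals over all 4-mer windows; the
  value is unnormalised and comparable across models only for the same
  sequence (and across sequences only at equal evaluated length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .formats_io import ScaffoldRecord

log = logging.getLogger("magdecon")

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

#: index permutation sending each k-mer code to its reverse complement
def _revcomp_perm(k: int) -> np.ndarray:
    codes = np.arange(4 ** k)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    return rc


_RC4 = _revcomp_perm(4)


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement k-mer codes elementwise (no 4^k lookup table, so
    usable for large k)."""
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    return rc


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes A=0 C=1 G=2 T=3, N (or anything
    else) = -1."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k-mer integer codes for every window, plus a validity mask (windows
    containing N are invalid)."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = arr[j : j + n]
        codes = codes * 4 + np.maximum(col, 0)
        valid &= col >= 0
    return codes, valid


def count_kmers(seq: str, k: int, strand_mode: str = "forward") -> np.ndarray:
    """Count k-mer occurrences; windows containing N are skipped.

    ``strand_mode='both'`` adds, for each motif, the occurrences of its
    reverse complement (equivalent to counting the forward strand of the
    sequence and of its reverse complement together).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"strand_mode {strand_mode!r}")
    arr = encode_sequence(seq)
    codes, valid = _window_codes(arr, k)
    counts = np.bincount(codes[valid], minlength=4 ** k).astype(np.int64)
    if strand_mode == "both":
        perm = _RC4 if k == 4 else _revcomp_perm(k)
        counts = counts + counts[perm]
    return counts


# ---------------------------------------------------------------------------
# TETRA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TetraSignature:
    z: np.ndarray  # 256 z-scores

    def __post_init__(self) -> None:
        if self.z.shape != (256,) or not np.all(np.isfinite(self.z)):
            raise ValueError("TETRA signature must be 256 finite z-scores")


def tetra_zscores(seq: str, min_len: int = 1000) -> TetraSignature:
    """TETRA z-score signature of a sequence (both-strand counting).

    Sequences shorter than ``min_len`` give unstable signatures; concatenate
    scaffolds (coverage-sorted) before calling.
    """
    if len(seq) < min_len:
        raise ValueError(
            f"sequence of {len(seq)} bp below the {min_len} bp floor; "
            "concatenate scaffolds before computing a TETRA signature"
        )
    n4 = count_kmers(seq, 4, "both").astype(np.float64)
    n3 = count_kmers(seq, 3, "both").astype(np.float64)
    n2 = count_kmers(seq, 2, "both").astype(np.float64)

    idx = np.arange(256)
    left3 = idx // 4          # n1n2n3
    right3 = idx % 64         # n2n3n4
    mid2 = left3 % 16         # n2n3

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n2[mid2]
        exp = n3[left3] * n3[right3] / denom
        var = exp * (n3[left3] - denom) * (n3[right3] - denom) / denom ** 2
        z = (n4 - exp) / np.sqrt(var)
    # zero-variance / unobserved-context motifs, and variances below one
    # squared count (numerically meaningless on degenerate sequences)
    z[~np.isfinite(z) | (var < 1.0)] = 0.0
    return TetraSignature(z)


def tetra_correlation(sig_a: TetraSignature, sig_b: TetraSignature) -> float:
    """Pearson correlation of two TETRA z-vectors — the "TETRA value"."""
    a, b = sig_a.z, sig_b.z
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        log.warning("constant TETRA signature: correlation undefined, returning 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# naive Bayesian classifier (order-3 Markov chain, forward strand)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifModel:
    """Per-component order-3 Markov model: log P(base | preceding 3-mer)."""

    label: str
    cond_logp: np.ndarray  # 64 contexts x 4 bases
    pseudocount: float
    trained_bp: int

    def __post_init__(self) -> None:
        if self.cond_logp.shape != (64, 4):
            raise ValueError("cond_logp must be 64x4")
        probs = np.exp(self.cond_logp)
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("conditional probabilities must sum to 1 per context")


def train_nb_model(
    records: list[ScaffoldRecord] | list[str],
    label: str,
    pseudocount: float = 1.0,
    min_bp: int = 10_000,
) -> MotifModel:
    """Train an order-3 Markov model from training sequences.

    Transition counts get an additive ``pseudocount``; contexts never observed
    therefore fall back to a uniform distribution.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    seqs = [r.seq if isinstance(r, ScaffoldRecord) else r for r in records]
    if not seqs:
        raise ValueError("empty training set")
    total_bp = sum(len(s) for s in seqs)
    if total_bp < min_bp:
        raise ValueError(f"{total_bp} training bp below the {min_bp} bp floor")
    trans = np.zeros((64, 4), dtype=np.float64)
    for s in seqs:
        arr = encode_sequence(s)
        codes, valid = _window_codes(arr, 4)
        codes = codes[valid]
        if codes.size:
            flat = np.bincount(codes, minlength=256)
            trans += flat.reshape(64, 4)
    trans += pseudocount
    cond_logp = np.log(trans) - np.log(trans.sum(axis=1, keepdims=True))
    return MotifModel(label, cond_logp, pseudocount, total_bp)


def nb_log_posterior(model: MotifModel, seq: str, prior: float = 1.0) -> float:
    """Unnormalised log posterior of ``seq`` under ``model``.

    Sum of log P(base_i | bases_{i-3..i-1}) over every 4-mer window not
    containing N, plus log(prior) (uniform priors cancel across models, so the
    default contributes 0). Comparable across models for the same sequence;
    across sequences only at equal evaluated length.
    """
    if len(seq) < 4:
        raise ValueError("sequence shorter than 4 bp cannot be scored")
    arr = encode_sequence(seq)
    codes, valid = _window_codes(arr, 4)
    codes = codes[valid]
    if codes.size == 0:
        raise ValueError("no N-free 4-mer window to score")
    flat = model.cond_logp.reshape(256)
    return float(flat[codes].sum() + np.log(prior))


@dataclass(frozen=True)
class ClassifierResult:
    best_label: str
    log_posterior: dict[str, float]
    margin: float
    tie: bool = False


def nb_classify(models: list[MotifModel], seq: str) -> ClassifierResult:
    """Assign ``seq`` to the model with the highest posterior.

    Exact ties go to the lexicographically smallest label and are logged.
    """
    if len(models) < 2:
        raise ValueError("classification needs at least 2 models")
    scores = {m.label: nb_log_posterior(m, seq) for m in models}
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_label, best = ordered[0]
    second = ordered[1][1]
    tie = best == second
    if tie:
        log.warning("posterior tie at %.6g; choosing %r lexicographically", best, best_label)
    return ClassifierResult(best_label, scores, best - second, tie=tie)


def model_to_json(model: MotifModel) -> str:
    """Serialise a motif model to JSON (64x4 log-probability table)."""
    import json
    return json.dumps({"label": model.label, "pseudocount": model.pseudocount,
                       "trained_bp": model.trained_bp,
                       "cond_logp": model.cond_logp.tolist()})


def model_from_json(text: str) -> MotifModel:
    import json
    d = json.loads(text)
    return MotifModel(d["label"], np.array(d["cond_logp"]), d["pseudocount"], d["trained_bp"])


def signature_to_json(sig: TetraSignature) -> str:
    import json
    return json.dumps({"z": sig.z.tolist()})


def signature_from_json(text: str) -> TetraSignature:
    import json
    return TetraSignature(np.array(json.loads(text)["z"]))


def nb_scores_batch(models: list[MotifModel], seqs: list[str]) -> np.ndarray:
    """Log posteriors for many sequences x models (vectorised inner loop)."""
    out = np.empty((len(seqs), len(models)))
    flats = [m.cond_logp.reshape(256) for m in models]
    for i, s in enumerate(seqs):
        arr = encode_sequence(s)
        codes, valid = _window_codes(arr, 4)
        codes = codes[valid]
        if codes.size == 0:
            raise ValueError(f"sequence {i}: no scorable window")
        counts = np.bincount(codes, minlength=256)
        for j, flat in enumerate(flats):
            out[i, j] = counts @ flat
    return out
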