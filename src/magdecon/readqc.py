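"""Unmapped-read triage.

Under deep sequencing every true genomic 15-mer is seen many times, so a
read containing a 15-mer observed at most twice in the whole read set almost
certainly carries a sequencing error (one wrong base corrupts k consecutive
k-mers). The triage counts canonical (strand-merged) 15-mer frequencies,
flags reads by a rare-k-mer rule, reports the low-quality fraction, and
tests — by a 2x2 chi-squared — whether high-quality reads are used by the
assembler more than low-quality ones.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .composition import encode_sequence, _window_codes, revcomp_codes

log = logging.getLogger("magdecon")

P_FLOOR = 2.2e-16


@dataclass(frozen=True)
class ReadFlagSummary:
    n_low: int
    n_high: int
    rule: str

    @property
    def total(self) -> int:
        return self.n_low + self.n_high


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float       # floored at 2.2e-16
    log_p: float         # exact natural-log p
    below_floor: bool


def _canonical_kmer_counts(reads: list[str], k: int) -> Counter:
    counts: Counter = Counter()
    for seq in reads:
        codes, valid = _window_codes(encode_sequence(seq), k)
        codes = codes[valid]
        if codes.size:
            canon = np.minimum(codes, revcomp_codes(codes, k))
            counts.update(canon.tolist())
    return counts


def kmer_flag_reads(
    reads: list[str],
    k: int = 15,
    freq_threshold: int = 2,
    rule: str = "any",
) -> tuple[ReadFlagSummary, list[str]]:
    """Flag each read low/high quality by the frequency of its k-mers.

    Frequencies are canonical k-mer counts over the full input read set.
    ``rule='any'`` flags a read low if at least one of its k-mers has
    frequency <= threshold; ``rule='all'`` only if every k-mer does. Reads
    shorter than k (or with no N-free k-mer) get the distinct 'too_short'
    low flag.
    """
    if not reads:
        raise ValueError("empty read set")
    if rule not in ("any", "all"):
        raise ValueError(f"rule {rule!r} (expected 'any' or 'all')")
    counts = _canonical_kmer_counts(reads, k)
    flags: list[str] = []
    for seq in reads:
        codes, valid = _window_codes(encode_sequence(seq), k)
        codes = codes[valid]
        if codes.size == 0:
            flags.append("too_short")
            continue
        canon = np.minimum(codes, revcomp_codes(codes, k))
        rare = [counts[c] <= freq_threshold for c in canon.tolist()]
        low = any(rare) if rule == "any" else all(rare)
        flags.append("low" if low else "high")
    n_high = flags.count("high")
    summary = ReadFlagSummary(len(flags) - n_high, n_high,
                              f"{rule} {k}-mer with frequency <= {freq_threshold}")
    return summary, flags


def low_quality_fraction(n_low: int, n_high: int) -> float:
    """Percent of evaluated reads flagged low quality, at two decimals."""
    total = n_low + n_high
    if total < 1:
        raise ValueError("no reads evaluated")
    return round(100.0 * n_low / total, 2)


def usage_chi2(
    used_high: int,
    total_high: int,
    used_low: int,
    total_low: int,
    correction: str = "yates",
) -> Chi2Result:
    """Pearson chi-squared on the 2x2 used/unused x high/low-quality table.

    ``correction`` is 'yates' (the common default for 2x2 tables) or 'none'.
    The reported p is floored at 2.2e-16; the exact log-p is also returned.
    """
    if not (0 <= used_high <= total_high and 0 <= used_low <= total_low):
        raise ValueError("need 0 <= used <= total in each arm")
    if total_high < 1 or total_low < 1:
        raise ValueError("totals must be >= 1")
    if correction not in ("yates", "none"):
        raise ValueError(f"correction {correction!r}")
    table = np.array([[used_high, total_high - used_high],
                      [used_low, total_low - used_low]], dtype=float)
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        raise ValueError("degenerate 2x2 table (empty row or column)")
    expected = stats.contingency.expected_freq(table)
    if expected.min() < 1:
        warnings.warn("expected cell count < 1; chi-squared approximation unreliable")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=(correction == "yates"))
    log_p = float(stats.chi2.logsf(chi2, 1)) if chi2 > 0 else 0.0
    return Chi2Result(float(chi2), max(float(p), P_FLOOR), log_p, p < P_FLOOR)
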