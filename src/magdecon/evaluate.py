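"""Binning-evaluation metrics over a bp-weighted bin x genome contingency
matrix.

With S_ij = base pairs of genome j placed in bin i:

    Precision   = sum_i max_j S_ij / sum_ij S_ij
    Sensitivity = sum_j max_i S_ij / (sum_ij S_ij + unbinned bp)
    F-score     = 2 P S / (P + S)

A bin is *correct* when it is the largest bin of its dominant genome; bins
sharing a dominant genome beyond the largest one count as incorrect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("magdecon")


@dataclass
class SijMatrix:
    S: pd.DataFrame          # rows = bins, cols = genomes, entries = bp
    unbinned_bp: int

    @property
    def total_binned(self) -> int:
        return int(self.S.to_numpy().sum())


@dataclass(frozen=True)
class MetricsResult:
    precision_pct: float
    sensitivity_pct: float
    fscore_pct: float
    n_correct_bins: int
    n_other_bins: int


def build_sij(
    gold: Mapping[str, str],
    bins: Mapping[str, str],
    scaffold_lengths: Mapping[str, int],
) -> SijMatrix:
    """Accumulate scaffold lengths into the bin x genome matrix; scaffolds in
    gold but absent from ``bins`` accumulate into unbinned bp."""
    for scaf in bins:
        if scaf not in gold:
            raise ValueError(f"binned scaffold {scaf!r} missing from gold standard")
    bin_labels = sorted(set(bins.values()))
    genome_labels = sorted(set(gold.values()))
    S = pd.DataFrame(0, index=bin_labels, columns=genome_labels, dtype=np.int64)
    unbinned = 0
    for scaf, genome in gold.items():
        length = scaffold_lengths[scaf]
        if scaf in bins:
            S.loc[bins[scaf], genome] += length
        else:
            unbinned += length
    return SijMatrix(S, unbinned)


def precision_sensitivity_fscore(sij: SijMatrix) -> MetricsResult:
    """Evaluate the three formulas on the 0-100 scale (two decimals)."""
    S = sij.S.to_numpy(dtype=float)
    total = S.sum()
    if total <= 0:
        raise ValueError("no binned base pairs")
    precision = S.max(axis=1).sum() / total
    sensitivity = S.max(axis=0).sum() / (total + sij.unbinned_bp)
    f = 2 * precision * sensitivity / (precision + sensitivity) if precision + sensitivity else 0.0
    n_correct, n_other = correct_bin_count(sij)
    return MetricsResult(round(100 * precision, 2), round(100 * sensitivity, 2),
                         round(100 * f, 2), n_correct, n_other)


def correct_bin_count(sij: SijMatrix) -> tuple[int, int]:
    """Count correct bins: each bin keeps its dominant genome (ties:
    lexicographically smallest genome, logged); among bins dominated by the
    same genome only the one holding the most bp of it is correct (ties:
    lexicographically smallest bin)."""
    S = sij.S
    if S.to_numpy().sum() <= 0:
        raise ValueError("no binned base pairs")
    dominant: dict[str, str] = {}
    for b in S.index:
        row = S.loc[b]
        top = row.max()
        winners = sorted(row.index[row == top])
        if len(winners) > 1:
            log.warning("bin %s: dominant-genome tie %s; keeping %s", b, winners, winners[0])
        dominant[b] = winners[0]
    correct = 0
    for genome in sorted(set(dominant.values())):
        contenders = sorted(b for b, g in dominant.items() if g == genome)
        best = max(contenders, key=lambda b: (S.loc[b, genome], ))
        tied = [b for b in contenders if S.loc[b, genome] == S.loc[best, genome]]
        if len(tied) > 1:
            log.warning("genome %s: bin-size tie %s; keeping %s", genome, tied, sorted(tied)[0])
        correct += 1
    return correct, len(S.index) - correct


def evaluation_report(
    gold: Mapping[str, str],
    bin_tables: Mapping[str, Mapping[str, str]],
    scaffold_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-binner metrics table plus the percentage of recovered base pairs."""
    if not bin_tables:
        raise ValueError("no bin tables")
    rows = []
    for name in sorted(bin_tables):
        sij = build_sij(gold, bin_tables[name], scaffold_lengths)
        try:
            m = precision_sensitivity_fscore(sij)
            recovered = round(100 * sij.total_binned / (sij.total_binned + sij.unbinned_bp), 2)
            rows.append({"binner": name, "precision_pct": m.precision_pct,
                         "sensitivity_pct": m.sensitivity_pct, "fscore_pct": m.fscore_pct,
                         "n_correct_bins": m.n_correct_bins, "n_other_bins": m.n_other_bins,
                         "recovered_pct": recovered, "degenerate": False})
        except ValueError:
            rows.append({"binner": name, "precision_pct": np.nan, "sensitivity_pct": np.nan,
                         "fscore_pct": np.nan, "n_correct_bins": 0, "n_other_bins": 0,
                         "recovered_pct": 0.0, "degenerate": True})
    return pd.DataFrame(rows).set_index("binner")
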