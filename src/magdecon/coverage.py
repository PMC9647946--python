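"""Sequencing-coverage summaries, per-component coverage ranges, range-based
scaffold assignment, and unimodality checks.

Per-scaffold depth is the mean over the scaffold after discarding 100 bp at
each end (coverage dips at scaffold ends); windowed depth uses a 500-bp
window sliding by 250 bp. Components occupy closed depth intervals [lo, hi];
a scaffold whose depth falls in exactly one interval is assignable by
coverage alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

log = logging.getLogger("magdecon")


@dataclass(frozen=True)
class CoverageSummary:
    scaffold_id: str
    mean_depth: float
    length: int
    trimmed: bool


@dataclass(frozen=True)
class WindowSeries:
    scaffold_id: str
    window: int
    step: int
    values: np.ndarray


@dataclass(frozen=True)
class CoverageRange:
    label: str
    lo: float
    hi: float
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise ValueError(f"range {self.label}: need 0 <= lo <= hi, got [{self.lo}, {self.hi}]")

    def contains(self, depth: float) -> bool:
        return self.lo <= depth <= self.hi


@dataclass(frozen=True)
class RangeAssignment:
    status: str  # assigned | ambiguous | none
    labels: tuple[str, ...]


@dataclass(frozen=True)
class PeakReport:
    n_peaks: int
    main_peak: bool
    bin_width: float


def scaffold_mean_coverage(depth_series: np.ndarray, trim: int = 100,
                           scaffold_id: str = "") -> CoverageSummary:
    """Mean depth after discarding ``trim`` bp at each end.

    Scaffolds of length <= 2*trim are averaged untrimmed (flagged, warned).
    """
    depth_series = np.asarray(depth_series, dtype=float)
    if depth_series.size == 0:
        raise ValueError("empty depth series")
    if (depth_series < 0).any():
        raise ValueError("negative depths")
    if trim < 0:
        raise ValueError("trim must be >= 0")
    L = depth_series.size
    if L > 2 * trim:
        return CoverageSummary(scaffold_id, float(depth_series[trim : L - trim].mean()), L, trim > 0)
    log.warning("scaffold %s (%d bp) too short for %d-bp end trim; untrimmed mean",
                scaffold_id or "?", L, trim)
    return CoverageSummary(scaffold_id, float(depth_series.mean()), L, False)


def windowed_coverage(depth_series: np.ndarray, window: int = 500, step: int = 250,
                      scaffold_id: str = "") -> WindowSeries:
    """Window means 5'->3': full windows start at 1, 1+step, ...; if the last
    full window ends before the scaffold end, a final window covering the last
    ``window`` bp is appended. A scaffold shorter than the window yields one
    whole-scaffold window."""
    depth_series = np.asarray(depth_series, dtype=float)
    if depth_series.size == 0:
        raise ValueError("empty depth series")
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    L = depth_series.size
    if L < window:
        return WindowSeries(scaffold_id, window, step, np.array([depth_series.mean()]))
    values = []
    last_end = 0
    for start in range(0, L - window + 1, step):
        values.append(depth_series[start : start + window].mean())
        last_end = start + window
    if last_end < L:
        values.append(depth_series[L - window :].mean())
    return WindowSeries(scaffold_id, window, step, np.array(values))


def infer_coverage_range(
    summaries: list[CoverageSummary],
    label: str = "",
    outlier_policy: str = "auto",
    factor: float = 10.0,
    exclude_ids: tuple[str, ...] = (),
) -> CoverageRange:
    """(lo, hi) = min/max scaffold depth of a component after outlier removal.

    Policies: ``none``; ``explicit`` (drop ``exclude_ids``); ``auto`` (drop
    scaffolds with depth > factor x median — the abnormally-high-coverage,
    plasmid-like scaffolds every component carries a few of).
    """
    if not summaries:
        raise ValueError("no coverage summaries")
    if outlier_policy == "none":
        kept, dropped = summaries, []
    elif outlier_policy == "explicit":
        kept = [s for s in summaries if s.scaffold_id not in set(exclude_ids)]
        dropped = [s for s in summaries if s.scaffold_id in set(exclude_ids)]
    elif outlier_policy == "auto":
        med = float(np.median([s.mean_depth for s in summaries]))
        kept = [s for s in summaries if s.mean_depth <= factor * med]
        dropped = [s for s in summaries if s.mean_depth > factor * med]
    else:
        raise ValueError(f"unknown outlier policy {outlier_policy!r}")
    if not kept:
        raise ValueError(f"range {label}: all scaffolds excluded by outlier policy")
    for s in dropped:
        log.info("range %s: excluding high-coverage scaffold %s (%.1fx)",
                 label, s.scaffold_id, s.mean_depth)
    depths = [s.mean_depth for s in kept]
    return CoverageRange(label, min(depths), max(depths),
                         tuple(sorted(s.scaffold_id for s in dropped)))


def assign_by_range(mean_depth: float, ranges: list[CoverageRange]) -> RangeAssignment:
    """Assign a depth to the unique closed interval containing it; ambiguous
    if several contain it, none if none does."""
    if not ranges:
        raise ValueError("no coverage ranges")
    inside = tuple(sorted(r.label for r in ranges if r.contains(mean_depth)))
    if len(inside) == 1:
        return RangeAssignment("assigned", inside)
    if len(inside) >= 2:
        return RangeAssignment("ambiguous", inside)
    return RangeAssignment("none", ())


def unimodality_check(values: np.ndarray, bin_width: float | None = None,
                      min_height_frac: float = 0.05) -> PeakReport:
    """Count main peaks in the distribution of windowed depths.

    Histogram at ``bin_width`` (default Freedman-Diaconis, falling back to
    1.0-fold), smoothed by a 3-bin moving average; peaks are local maxima with
    height >= ``min_height_frac`` of the modal bin. A well-reconstructed MAG
    shows exactly one main peak.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 30:
        raise ValueError("need >= 30 window values; use whole-scaffold means instead")
    if bin_width is None:
        iqr = float(np.subtract(*np.percentile(values, [75, 25])))
        bin_width = 2 * iqr * values.size ** (-1 / 3)
        if bin_width <= 0:
            bin_width = 1.0
    lo, hi = values.min(), values.max()
    nbins = max(1, int(np.ceil((hi - lo) / bin_width)) + 1)
    hist, _ = np.histogram(values, bins=nbins, range=(lo, lo + nbins * bin_width))
    smooth = np.convolve(hist, np.ones(3) / 3, mode="same")
    padded = np.concatenate([[0.0], smooth, [0.0]])  # let edge bins be peaks
    peaks, _ = find_peaks(padded, height=min_height_frac * smooth.max())
    n = int(len(peaks))
    return PeakReport(n, n == 1, float(bin_width))
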