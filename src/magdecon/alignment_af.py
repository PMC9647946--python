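"""Alignment fractions: the per-(scaffold, isolate) percentage of a
metagenome scaffold covered by merged alignments to an isolate genome.

AF is computed on the query (scaffold) axis, because assignment decisions are
made per scaffold. Hits shorter than 200 bp on the query are dropped first,
mirroring the usual delta-filter length floor; best-hit chaining is assumed
already applied upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .formats_io import AlignmentHit, ScaffoldRecord


@dataclass(frozen=True)
class AFRecord:
    scaffold_id: str
    isolate_label: str
    af_pct: float
    covered_bp: int
    scaffold_len: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.af_pct <= 100.0):
            raise ValueError(f"AF {self.af_pct} outside [0, 100]")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals into a disjoint sorted union;
    touching intervals ([1,5],[6,9]) merge."""
    ivals = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivals:
        if start > end:
            raise ValueError(f"interval ({start}, {end}) has start > end")
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def alignment_fraction(scaffold_len: int, intervals: Iterable[tuple[int, int]]) -> tuple[int, float]:
    """(covered_bp, af_pct) from merged intervals on one scaffold."""
    if scaffold_len < 1:
        raise ValueError("scaffold_len must be >= 1")
    merged = merge_intervals(intervals)
    if merged and (merged[0][0] < 1 or merged[-1][1] > scaffold_len):
        raise ValueError(f"interval outside [1, {scaffold_len}]")
    covered = sum(e - s + 1 for s, e in merged)
    return covered, 100.0 * covered / scaffold_len


def af_table(
    hits: Iterable[AlignmentHit],
    scaffolds: Mapping[str, int] | list[ScaffoldRecord],
    min_hit_len: int = 200,
) -> list[AFRecord]:
    """One AFRecord per (scaffold, isolate) pair with at least one hit of
    query length >= ``min_hit_len``."""
    if not isinstance(scaffolds, Mapping):
        scaffolds = {r.id: r.length for r in scaffolds}
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in hits:
        if h.qry_id not in scaffolds:
            raise ValueError(f"hit references unknown scaffold {h.qry_id!r}")
        if h.qry_len < min_hit_len:
            continue
        grouped.setdefault((h.qry_id, h.ref_id), []).append((h.qry_start, h.qry_end))
    records = []
    for (scaf, iso), ivals in sorted(grouped.items()):
        covered, af = alignment_fraction(scaffolds[scaf], ivals)
        records.append(AFRecord(scaf, iso, af, covered, scaffolds[scaf]))
    return records
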