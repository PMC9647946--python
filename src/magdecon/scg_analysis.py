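"""Single-copy-gene (SCG) bookkeeping.

Essential SCGs are expected exactly once per genome, so a bin whose SCG copy
table shows wholesale duplication is almost certainly two merged genomes.
Completeness is the number of distinct SCGs present divided by the size of
the marker universe (107 for the Firmicutes-style set used here). SCG AAI —
protein-length-weighted mean amino-acid identity over matched SCGs — ranks
candidate reference genomes; a comparison counts only if more than 95% of
the smaller genome's SCGs are matched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

log = logging.getLogger("magdecon")

DEFAULT_UNIVERSE_SIZE = 107


@dataclass(frozen=True)
class SCGHit:
    gene_id: str
    scaffold_id: str
    scg_id: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"gene {self.gene_id}: e-value must be positive")


@dataclass
class SCGCopyTable:
    """Per-MAG SCG copy counts plus scaffold-level bookkeeping."""

    counts: dict[str, dict[str, int]]                 # mag -> scg -> copies
    scg_scaffolds: dict[str, set[str]]                # mag -> SCG-bearing scaffolds
    multicopy_scaffolds: dict[str, set[str]]          # mag -> scaffolds bearing a >1-copy SCG
    suspect_merge: dict[str, bool]                    # mag -> merged-bin flag


@dataclass(frozen=True)
class AAIResult:
    genome_a: str
    genome_b: str
    weighted_identity_pct: float
    mapped_fraction: float

    @property
    def valid(self) -> bool:
        return self.mapped_fraction > 0.95


def resolve_annotations(raw_hits: Iterable[SCGHit]) -> list[SCGHit]:
    """Keep, per gene, only the SCG annotation with the minimum e-value
    (exact ties: lexicographically smallest scg_id, logged)."""
    best: dict[str, SCGHit] = {}
    for h in raw_hits:
        cur = best.get(h.gene_id)
        if cur is None or (h.evalue, h.scg_id) < (cur.evalue, cur.scg_id):
            if cur is not None and h.evalue == cur.evalue:
                log.warning("gene %s: e-value tie %g; keeping %s lexicographically",
                            h.gene_id, h.evalue, h.scg_id)
            best[h.gene_id] = h
    return [best[g] for g in sorted(best)]


def scg_copy_table(
    resolved_hits: Iterable[SCGHit],
    bin_assignment: Mapping[str, str | None],
    merge_flag_frac: float = 0.25,
) -> SCGCopyTable:
    """Aggregate resolved SCG hits into per-MAG copy counts.

    ``bin_assignment`` maps scaffold -> bin label (None = explicitly
    unbinned). A bin where >= ``merge_flag_frac`` of present SCGs occur in
    more than one copy is flagged ``suspect_merge`` — the signature of two
    genomes sharing one bin.
    """
    counts: dict[str, dict[str, int]] = {}
    scafs: dict[str, set[str]] = {}
    scg_locations: dict[str, dict[str, set[str]]] = {}  # mag -> scg -> scaffolds
    for mag in set(bin_assignment.values()):
        if mag is not None:
            counts[mag] = {}
            scafs[mag] = set()
            scg_locations[mag] = {}
    for h in resolved_hits:
        if h.scaffold_id not in bin_assignment:
            raise ValueError(f"SCG hit on unknown scaffold {h.scaffold_id!r}")
        mag = bin_assignment[h.scaffold_id]
        if mag is None:
            continue
        counts[mag][h.scg_id] = counts[mag].get(h.scg_id, 0) + 1
        scafs[mag].add(h.scaffold_id)
        scg_locations[mag].setdefault(h.scg_id, set()).add(h.scaffold_id)

    multicopy: dict[str, set[str]] = {}
    suspect: dict[str, bool] = {}
    for mag, row in counts.items():
        dup_scgs = {s for s, c in row.items() if c > 1}
        multicopy[mag] = set().union(*(scg_locations[mag][s] for s in dup_scgs)) if dup_scgs else set()
        suspect[mag] = bool(row) and len(dup_scgs) >= merge_flag_frac * len(row)
        if suspect[mag]:
            log.warning("bin %s: %d/%d SCGs multi-copy — suspected merged genomes",
                        mag, len(dup_scgs), len(row))
    return SCGCopyTable(counts, scafs, multicopy, suspect)


def completeness(copy_row: Mapping[str, int], universe_size: int = DEFAULT_UNIVERSE_SIZE) -> float:
    """Percent completeness: distinct SCGs present / universe size, at two
    decimals (65 of 107 -> 60.75)."""
    if universe_size < 1:
        raise ValueError("universe_size must be >= 1")
    present = sum(1 for c in copy_row.values() if c >= 1)
    return round(100.0 * present / universe_size, 2)


def scg_aai(
    matched_pairs: list[tuple[str, float, int]],
    total_a: int,
    total_b: int,
    genome_a: str = "a",
    genome_b: str = "b",
) -> AAIResult:
    """Protein-length-weighted AAI over matched SCGs.

    ``matched_pairs`` rows are (scg_id, identity_pct, protein_length_aa).
    mapped_fraction uses the smaller genome's SCG total as denominator (the
    conservative reading of the >95%-mapped validity rule).
    """
    if not matched_pairs:
        raise ValueError("no matched SCG pairs")
    wsum = sum(ident * length for _, ident, length in matched_pairs)
    lsum = sum(length for _, _, length in matched_pairs)
    if lsum <= 0:
        raise ValueError("non-positive total protein length")
    mapped = len(matched_pairs) / min(total_a, total_b)
    return AAIResult(genome_a, genome_b, wsum / lsum, mapped)


def closest_relatives(aai_results: list[AAIResult]) -> tuple[list[AAIResult], float]:
    """Rank valid AAI results descending; margin = top1 - top2 weighted
    identity (0, flagged in the log, with a single or tied top reference)."""
    valid = [r for r in aai_results if r.valid]
    if not valid:
        raise ValueError("no valid AAI comparison (need > 95% SCGs mapped)")
    ranked = sorted(valid, key=lambda r: (-r.weighted_identity_pct, r.genome_b))
    if len(ranked) == 1:
        log.info("single valid reference %s; margin undefined, reported 0", ranked[0].genome_b)
        return ranked, 0.0
    margin = ranked[0].weighted_identity_pct - ranked[1].weighted_identity_pct
    if margin == 0:
        log.warning("tied top references %s / %s", ranked[0].genome_b, ranked[1].genome_b)
    return ranked, margin


def concordance_count(per_scg_best_hits: Mapping[str, str], allowed_references: set[str]) -> float:
    """Percent of a MAG's SCG best hits landing in the allowed reference set
    (a set, so two jointly-employed closest relatives count together)."""
    if not per_scg_best_hits:
        raise ValueError("no SCG best hits")
    if not allowed_references:
        raise ValueError("empty allowed reference set")
    hit = sum(1 for ref in per_scg_best_hits.values() if ref in allowed_references)
    return 100.0 * hit / len(per_scg_best_hits)
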