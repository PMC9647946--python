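"""Readers/writers for the external formats the toolkit consumes, plus basic
assembly statistics.

All alignment coordinates are 1-based inclusive on both axes (the
``show-coords`` convention); conversion happens once, at parse time, and every
downstream interval computation keeps that convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("magdecon")

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ScaffoldRecord:
    """A named DNA sequence; the atom every pipeline stage moves."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"scaffold {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    total_bp: int
    n50: int
    max_len: int
    min_len_filter: int
    empty: bool = False


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment interval between an isolate genome (ref) and a
    metagenome scaffold (query), 1-based inclusive."""

    ref_id: str
    qry_id: str
    qry_start: int
    qry_end: int
    ref_start: int
    ref_end: int
    identity_pct: float
    reverse: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.qry_start <= self.qry_end):
            raise ValueError(
                f"hit {self.ref_id}/{self.qry_id}: bad query interval "
                f"[{self.qry_start}, {self.qry_end}]"
            )
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"identity {self.identity_pct} outside [0, 100]")

    @property
    def qry_len(self) -> int:
        return self.qry_end - self.qry_start + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, coerce_ambiguous: bool = False) -> list[ScaffoldRecord]:
    """Read a multi-record FASTA into :class:`ScaffoldRecord` objects.

    Lowercase input is uppercased. Characters outside {A,C,G,T,N} raise by
    default; with ``coerce_ambiguous=True`` they are mapped to N (IUPAC
    ambiguity codes are common in draft assemblies but carry no information
    the downstream k-mer machinery can use).
    """
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate scaffold id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            if coerce_ambiguous:
                seq = "".join(c if c in VALID_BASES else "N" for c in seq)
            else:
                raise ValueError(
                    f"scaffold {rec.id!r}: characters {sorted(bad)} outside "
                    "ACGTN (pass coerce_ambiguous=True to map them to N)"
                )
        records.append(ScaffoldRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ScaffoldRecord], path, line_width: int = 60) -> None:
    records = list(records)
    if not records:
        warnings.warn(f"writing empty FASTA to {path}")
        Path(path).write_text("")
        return
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, r.length, line_width):
                fh.write(r.seq[i : i + line_width] + "\n")


def assembly_stats(records: Iterable[ScaffoldRecord], min_len: int = 0) -> AssemblyStats:
    """Scaffold count, total bp, N50 and max length after a length filter.

    N50 is the length L such that scaffolds of length >= L, scanned in
    decreasing order, cover at least half of the filtered total.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    lengths = sorted((r.length for r in records if r.length >= min_len), reverse=True)
    if not lengths:
        return AssemblyStats(0, 0, 0, 0, min_len, empty=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc * 2 >= total:
            n50 = L
            break
    return AssemblyStats(len(lengths), total, n50, lengths[0], min_len)


# ---------------------------------------------------------------------------
# show-coords dialect
# ---------------------------------------------------------------------------

#: tab-separated column layout of `show-coords -c -l -r -T` family output
COORDS_COLUMNS = ("S1", "E1", "S2", "E2", "LEN1", "LEN2", "%IDY", "LENR", "LENQ", "ref_id", "qry_id")


def parse_coords_table(path) -> list[AlignmentHit]:
    """Parse a show-coords-style TSV into alignment hits.

    Header lines whose first token is non-numeric are skipped (the native
    4-line header is tolerated). Reverse-strand hits (descending query
    coordinates) are stored with ascending coordinates and flagged.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            try:
                int(parts[0])
            except ValueError:
                continue  # header / banner line
            if len(parts) < 11:
                raise ValueError(f"{path}:{lineno}: expected >=11 tab-separated columns, got {len(parts)}")
            try:
                s1, e1, s2, e2 = (int(parts[i]) for i in range(4))
                idy = float(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            ref_id, qry_id = parts[9], parts[10]
            reverse = s2 > e2
            if reverse:
                s2, e2 = e2, s2
            if s1 > e1:
                s1, e1 = e1, s1
            hits.append(AlignmentHit(ref_id, qry_id, s2, e2, s1, e1, idy, reverse=reverse))
    return hits


def write_coords_table(hits: Iterable[AlignmentHit], path) -> None:
    """Emit hits back into the accepted dialect (round-trips through
    :func:`parse_coords_table`)."""
    with open(path, "w") as fh:
        fh.write("\t".join(COORDS_COLUMNS) + "\n")
        for h in hits:
            s2, e2 = (h.qry_end, h.qry_start) if h.reverse else (h.qry_start, h.qry_end)
            len1 = h.ref_end - h.ref_start + 1
            len2 = h.qry_end - h.qry_start + 1
            fh.write(
                f"{h.ref_start}\t{h.ref_end}\t{s2}\t{e2}\t{len1}\t{len2}\t"
                f"{h.identity_pct}\t0\t0\t{h.ref_id}\t{h.qry_id}\n"
            )


# ---------------------------------------------------------------------------
# depth tables
# ---------------------------------------------------------------------------

def parse_depth_table(path, scaffold_lengths: Mapping[str, int] | None = None) -> dict[str, np.ndarray]:
    """Parse a 3-column (scaffold, 1-based position, depth) TSV into dense
    per-base depth arrays. Missing positions are depth 0 when the scaffold
    length is known."""
    df = pd.read_csv(path, sep="\t", header=None, names=["scaffold", "pos", "depth"],
                     dtype={"scaffold": str, "pos": np.int64, "depth": np.float64})
    table: dict[str, np.ndarray] = {}
    for scaf, grp in df.groupby("scaffold", sort=False):
        pos = grp["pos"].to_numpy()
        if (pos < 1).any():
            raise ValueError(f"scaffold {scaf}: positions must be 1-based")
        if (grp["depth"] < 0).any():
            raise ValueError(f"scaffold {scaf}: negative depth")
        length = int(pos.max())
        if scaffold_lengths is not None and scaf in scaffold_lengths:
            declared = scaffold_lengths[scaf]
            if length > declared:
                raise ValueError(
                    f"scaffold {scaf}: position {length} exceeds declared length {declared}"
                )
            length = declared
        dense = np.zeros(length, dtype=np.float64)
        dense[pos - 1] = grp["depth"].to_numpy()
        table[scaf] = dense
    return table


def write_depth_table(table: Mapping[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for scaf, depths in table.items():
            for i, d in enumerate(depths, start=1):
                fh.write(f"{scaf}\t{i}\t{d:g}\n")


def read_coverage_summary(path) -> pd.DataFrame:
    """Per-scaffold coverage summary (scaffold/mean_depth/length TSV).

    This form bypasses the 100-bp end trimming of per-base input; a warning is
    logged because end effects are then the caller's responsibility.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"scaffold", "mean_depth", "length"} - set(df.columns)
    if missing:
        raise ValueError(f"coverage summary missing columns {sorted(missing)}")
    log.warning("per-scaffold summary input bypasses end-trimming")
    return df


# ---------------------------------------------------------------------------
# assignment tables (SCG hits, binner outputs, gold standards)
# ---------------------------------------------------------------------------

def parse_assignment_table(path, kind: str) -> pd.DataFrame:
    """Parse SCG-hit (`kind='scg'`) or scaffold->label (`kind='bin'|'gold'`)
    TSVs.

    SCG rows are (gene_id, scaffold_id, scg_id, evalue); bin/gold rows are
    (scaffold_id, label). A scaffold listed under two different bins is an
    error — a scaffold belongs to one bin.
    """
    if kind == "scg":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["gene_id", "scaffold_id", "scg_id", "evalue"],
                         dtype=str)
        df["evalue"] = [float(v) for v in df["evalue"]]  # exact round-trip parse
        if (df["evalue"] <= 0).any():
            raise ValueError("SCG e-values must be positive")
        return df
    if kind in ("bin", "gold"):
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["scaffold_id", "label"],
                         dtype={"scaffold_id": str, "label": str})
        conflicts = df.groupby("scaffold_id")["label"].nunique()
        dupes = conflicts[conflicts > 1]
        if not dupes.empty:
            raise ValueError(
                f"scaffolds assigned to multiple bins: {sorted(dupes.index)[:5]}"
            )
        return df.drop_duplicates()
    raise ValueError(f"unknown table kind {kind!r} (expected scg, bin or gold)")


def write_assignment_table(mapping: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for scaf, label in mapping.items():
            fh.write(f"{scaf}\t{label}\n")
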