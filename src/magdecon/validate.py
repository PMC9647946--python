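"""Composition-based reconstruction validation.

Each MAG's scaffolds are sorted by decreasing sequencing coverage,
concatenated, and shredded into 10-kb fragments stepping every 5 kb. Each
fragment is classified back against whole-MAG composition models — TETRA
z-score correlation, or the naive Bayes classifier — and the fraction of
fragments returning to their own MAG, tabulated as a row-normalised
true-vs-predicted accuracy matrix, measures reconstruction reliability.
Short scaffolds (< 10 kb) are validated individually by naive Bayes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .composition import (MotifModel, TetraSignature, nb_classify,
                          tetra_correlation, tetra_zscores, train_nb_model)
from .coverage import CoverageSummary
from .formats_io import ScaffoldRecord

log = logging.getLogger("magdecon")


@dataclass(frozen=True)
class Fragment:
    source_mag: str
    index: int
    seq: str
    start_offset: int
    whole_genome: bool = False


def shred_mag(
    scaffolds: list[ScaffoldRecord],
    coverage_summaries: Mapping[str, CoverageSummary] | Mapping[str, float],
    fragment: int = 10_000,
    overlap: int = 5_000,
    source_mag: str = "",
) -> list[Fragment]:
    """Coverage-sorted concatenation followed by overlapping shredding.

    Scaffolds sort by mean depth descending (ties by id); fragments start at
    offsets 0, overlap, 2*overlap, ...; a final sub-length fragment at the
    next offset is kept iff it is at least ``overlap`` bp. A MAG shorter than
    one fragment yields a single flagged whole-genome fragment.
    """
    if not (fragment > overlap > 0):
        raise ValueError("need fragment > overlap > 0")

    def depth_of(scaf_id: str) -> float:
        c = coverage_summaries[scaf_id]
        return c.mean_depth if isinstance(c, CoverageSummary) else float(c)

    ordered = sorted(scaffolds, key=lambda r: (-depth_of(r.id), r.id))
    concat = "".join(r.seq for r in ordered)
    L = len(concat)
    if L < fragment:
        log.warning("MAG %s: %d bp shorter than one fragment; whole-genome fragment", source_mag, L)
        return [Fragment(source_mag, 0, concat, 0, whole_genome=True)]
    frags = []
    offset = 0
    while offset + fragment <= L:
        frags.append(Fragment(source_mag, len(frags), concat[offset : offset + fragment], offset))
        offset += overlap
    last_full_end = offset - overlap + fragment
    if last_full_end < L and L - offset >= overlap:
        frags.append(Fragment(source_mag, len(frags), concat[offset:], offset))
    return frags


def expected_fragment_count(L: int, fragment: int = 10_000, overlap: int = 5_000) -> int:
    """Closed-form fragment count for a concatenated length L (the shredding
    rule above, without building sequences)."""
    if L < fragment:
        return 1
    n_full = (L - fragment) // overlap + 1
    last_end = (n_full - 1) * overlap + fragment
    extra = 1 if (last_end < L and L - n_full * overlap >= overlap) else 0
    return n_full + extra


def _accuracy_matrix(true_pred: list[tuple[str, str]], labels: list[str]) -> tuple[pd.DataFrame, float]:
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for t, p in true_pred:
        mat.loc[t, p] += 1
    correct = sum(1 for t, p in true_pred if t == p)
    total_acc = 100.0 * correct / len(true_pred)
    row_sums = mat.sum(axis=1)
    mat = mat.div(row_sums.replace(0, np.nan), axis=0) * 100.0
    return mat, total_acc


def tetra_validate(
    mags: Mapping[str, list[ScaffoldRecord]],
    coverage_summaries: Mapping[str, CoverageSummary] | Mapping[str, float],
    classify_mode: str = "tetra",
    fragment: int = 10_000,
    overlap: int = 5_000,
) -> tuple[pd.DataFrame, float]:
    """Shred every MAG and classify fragments against whole-MAG models.

    Returns the row-normalised accuracy matrix (percent, rows = true MAG) and
    the total accuracy (fragment-count-weighted micro-average). With a single
    MAG the check degenerates to 100% trivially.
    """
    if classify_mode not in ("tetra", "nb"):
        raise ValueError(f"classify_mode {classify_mode!r}")
    labels = sorted(mags)
    frags_per_mag = {
        lab: shred_mag(mags[lab], coverage_summaries, fragment, overlap, lab) for lab in labels
    }
    for lab, frags in frags_per_mag.items():
        if not frags:
            raise ValueError(f"MAG {lab}: zero fragments")

    concat = {lab: "".join(r.seq for r in mags[lab]) for lab in labels}
    if classify_mode == "tetra":
        sigs = {lab: tetra_zscores(concat[lab]) for lab in labels}

        def predict(seq: str) -> str:
            fs = tetra_zscores(seq)
            scored = sorted(((-tetra_correlation(fs, sigs[lab]), lab) for lab in labels))
            return scored[0][1]
    else:
        models = [train_nb_model([concat[lab]], lab) for lab in labels]

        def predict(seq: str) -> str:
            if len(models) == 1:
                return models[0].label
            return nb_classify(models, seq).best_label

    true_pred = [
        (lab, predict(f.seq)) for lab in labels for f in frags_per_mag[lab]
    ]
    return _accuracy_matrix(true_pred, labels)


@dataclass
class ShortScaffoldReport:
    accuracy_pct: dict[str, float]   # per MAG; MAGs with no short scaffolds absent
    empty_mags: list[str]
    n_short: dict[str, int]


def short_scaffold_validate(
    mags: Mapping[str, list[ScaffoldRecord]],
    max_len: int = 10_000,
) -> ShortScaffoldReport:
    """Classify every scaffold shorter than ``max_len`` by naive Bayes over
    whole-MAG models; per-MAG accuracy is the percent returning home."""
    labels = sorted(mags)
    models = [train_nb_model([r.seq for r in mags[lab]], lab) for lab in labels]
    acc: dict[str, float] = {}
    empty: list[str] = []
    n_short: dict[str, int] = {}
    for lab in labels:
        short = [r for r in mags[lab] if r.length < max_len]
        n_short[lab] = len(short)
        if not short:
            empty.append(lab)
            continue
        correct = sum(1 for r in short if nb_classify(models, r.seq).best_label == lab)
        acc[lab] = 100.0 * correct / len(short)
    if not acc:
        log.warning("no scaffolds below %d bp in any MAG", max_len)
    return ShortScaffoldReport(acc, empty, n_short)
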