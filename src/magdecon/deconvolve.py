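"""The five-step isolate-guided MAG deconvolution pipeline.

Given metagenome scaffolds, isolate-vs-metagenome alignments, per-base depth
and single-copy-gene annotations:

1. alignment fractions (AF) per (scaffold, isolate) are computed;
2. scaffolds with AF >= 90% go to their isolate;
3. unaligned scaffolds inside exactly one component's coverage range go to
   that component (priming the uncultured MAGs); scaffolds inside several
   overlapping ranges are classified by naive Bayes among just those
   components;
4. remaining scaffolds (low AF, or outside all ranges) go by unique range
   where possible, otherwise by naive Bayes over all components — to an
   isolate only if that isolate also has an alignment on the scaffold, else
   to the best-scoring uncultured component;
5. a bin whose SCG table shows wholesale duplication is two merged genomes:
   its duplicate-marker scaffolds are scored against an external component's
   model, split at a posterior cutoff (numeric, or the midpoint of the
   largest score gap), and the two seed groups retrain models that
   re-classify the whole bin.

Every scaffold at or above the minimum length is assigned exactly once;
shorter scaffolds are excluded and listed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .alignment_af import AFRecord, af_table
from .composition import MotifModel, nb_classify, nb_log_posterior, train_nb_model
from .coverage import CoverageRange, CoverageSummary, assign_by_range, scaffold_mean_coverage
from .formats_io import AlignmentHit, ScaffoldRecord
from .scg_analysis import SCGHit, resolve_annotations, scg_copy_table

log = logging.getLogger("magdecon")

STEP_TAGS = ("step2", "step3_unique", "step3_nb", "step4_unique",
             "step4_nb_isolate", "step4_nb_uncultured", "step5")


@dataclass(frozen=True)
class Assignment:
    label: str
    step_tag: str
    detail: float | None = None  # AF, depth or posterior behind the decision


@dataclass(frozen=True)
class PipelineConfig:
    af_threshold: float = 90.0
    ranges: Mapping[str, CoverageRange] = field(default_factory=dict)
    pseudocount: float = 1.0
    posterior_cutoff: float | str = "auto"
    step5_per_window: bool = True
    min_scaffold_len: int = 500
    trim: int = 100
    min_hit_len: int = 200
    merge_flag_frac: float = 0.25
    min_training_bp: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.af_threshold <= 100):
            raise ValueError("af_threshold must be in (0, 100]")
        if self.min_scaffold_len < 1:
            raise ValueError("min_scaffold_len must be >= 1")


@dataclass
class PipelineResult:
    assignments: dict[str, Assignment]
    excluded_short: list[str]
    report: dict
    mags: dict[str, list[str]]           # component -> scaffold ids
    summaries: dict[str, CoverageSummary]
    af_records: list[AFRecord]


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------

def step2_assign_isolates(
    af_records: Iterable[AFRecord],
    af_threshold: float = 90.0,
) -> tuple[dict[str, Assignment], list[str], set[str]]:
    """Assign scaffolds with AF >= threshold to their isolate.

    Multi-isolate qualifiers go to the maximum AF (conflict logged). Returns
    (assignments, conflict log, deferred scaffolds with hits but all AF below
    threshold).
    """
    by_scaffold: dict[str, list[AFRecord]] = {}
    for rec in af_records:
        by_scaffold.setdefault(rec.scaffold_id, []).append(rec)
    assignments: dict[str, Assignment] = {}
    conflicts: list[str] = []
    deferred: set[str] = set()
    for scaf, recs in sorted(by_scaffold.items()):
        qualifying = [r for r in recs if r.af_pct >= af_threshold]
        if not qualifying:
            deferred.add(scaf)
            continue
        best = sorted(qualifying, key=lambda r: (-r.af_pct, r.isolate_label))[0]
        if len(qualifying) > 1:
            msg = (f"{scaf}: AF >= {af_threshold} for "
                   f"{sorted((r.isolate_label, r.af_pct) for r in qualifying)}; kept {best.isolate_label}")
            conflicts.append(msg)
            log.warning("step2 conflict: %s", msg)
        assignments[scaf] = Assignment(best.isolate_label, "step2", best.af_pct)
    return assignments, conflicts, deferred


def step3_assign_unaligned(
    unaligned: Iterable[str],
    summaries: Mapping[str, CoverageSummary],
    ranges: Mapping[str, CoverageRange],
    models: Mapping[str, MotifModel] | None,
    seqs: Mapping[str, str],
) -> tuple[dict[str, Assignment], set[str], list[str]]:
    """Assign unaligned scaffolds by unique coverage range; classify
    ambiguous-range scaffolds among just the overlapping components' models.

    Returns (assignments, deferred-to-step4, ambiguous scaffolds that had to
    wait for models when ``models`` is None).
    """
    assignments: dict[str, Assignment] = {}
    deferred: set[str] = set()
    pending_ambiguous: list[str] = []
    for scaf in sorted(unaligned):
        if scaf not in summaries:
            raise ValueError(f"no coverage summary for scaffold {scaf!r}")
        depth = summaries[scaf].mean_depth
        res = assign_by_range(depth, list(ranges.values()))
        if res.status == "assigned":
            assignments[scaf] = Assignment(res.labels[0], "step3_unique", depth)
        elif res.status == "ambiguous":
            if models is None:
                pending_ambiguous.append(scaf)
                continue
            cands = [models[lab] for lab in res.labels if lab in models]
            if len(cands) < 2:
                deferred.add(scaf)
                continue
            cls = nb_classify(cands, seqs[scaf])
            assignments[scaf] = Assignment(cls.best_label, "step3_nb",
                                           cls.log_posterior[cls.best_label])
        else:
            deferred.add(scaf)
    return assignments, deferred, pending_ambiguous


def step4_assign_low_af(
    deferred: Iterable[str],
    af_records: Iterable[AFRecord],
    summaries: Mapping[str, CoverageSummary],
    ranges: Mapping[str, CoverageRange],
    models: Mapping[str, MotifModel],
    isolate_labels: set[str],
    seqs: Mapping[str, str],
) -> dict[str, Assignment]:
    """Recover the remaining scaffolds.

    Unique coverage range wins outright; otherwise naive Bayes over all
    component models — the top isolate is accepted only when it also has an
    alignment on the scaffold, else the scaffold goes to the best-scoring
    uncultured component.
    """
    aligned_pairs = {(r.scaffold_id, r.isolate_label) for r in af_records}
    model_list = [models[lab] for lab in sorted(models)]
    assignments: dict[str, Assignment] = {}
    for scaf in sorted(deferred):
        depth = summaries[scaf].mean_depth
        res = assign_by_range(depth, list(ranges.values()))
        if res.status == "assigned":
            assignments[scaf] = Assignment(res.labels[0], "step4_unique", depth)
            continue
        cls = nb_classify(model_list, seqs[scaf])
        best = cls.best_label
        if best in isolate_labels:
            if (scaf, best) in aligned_pairs:
                assignments[scaf] = Assignment(best, "step4_nb_isolate",
                                               cls.log_posterior[best])
                continue
            uncultured = {lab: lp for lab, lp in cls.log_posterior.items()
                          if lab not in isolate_labels}
            if not uncultured:
                raise ValueError(f"{scaf}: top model is an unaligned isolate and "
                                 "no uncultured component exists")
            best = sorted(uncultured, key=lambda lab: (-uncultured[lab], lab))[0]
            assignments[scaf] = Assignment(best, "step4_nb_uncultured", uncultured[best])
        else:
            assignments[scaf] = Assignment(best, "step4_nb_uncultured",
                                           cls.log_posterior[best])
    return assignments


#: minimum fraction of score variance a two-cluster split must explain for
#: the distribution to count as bimodal (an optimal split of a single
#: Gaussian explains ~2/pi ~ 0.64)
BIMODALITY_MIN_EXPLAINED = 0.70


def split_scores_at_cutoff(
    scores: Mapping[str, float],
    cutoff: float | str = "auto",
) -> tuple[set[str], set[str], float]:
    """Split scored scaffolds into (above, below) groups at a posterior
    cutoff.

    ``cutoff='auto'`` places the threshold by an exhaustive two-means scan
    (the split of the sorted scores minimising within-cluster variance) and
    refuses to split unless the two clusters explain at least
    ``BIMODALITY_MIN_EXPLAINED`` of the total variance — the bimodality that
    a genuinely merged bin shows and a pure bin does not.
    """
    if len(scores) < 2:
        raise ValueError("need >= 2 scored scaffolds to split")
    ordered = sorted(scores.items(), key=lambda kv: -kv[1])
    vals = np.array([v for _, v in ordered])
    if cutoff == "auto":
        total_var = vals.var()
        if total_var == 0:
            raise ValueError("no bimodal separation: all scores identical")
        best_i, best_within = 0, np.inf
        for i in range(1, len(vals)):
            hi, lo = vals[:i], vals[i:]
            within = hi.size * hi.var() + lo.size * lo.var()
            if within < best_within:
                best_within, best_i = within, i
        explained = 1.0 - best_within / (vals.size * total_var)
        if explained < BIMODALITY_MIN_EXPLAINED:
            raise ValueError(
                "no bimodal separation in posterior scores "
                f"(two-cluster split explains {explained:.2f} of variance "
                f"< {BIMODALITY_MIN_EXPLAINED})")
        cut = (vals[best_i - 1] + vals[best_i]) / 2.0
    else:
        cut = float(cutoff)
    above = {k for k, v in scores.items() if v > cut}
    below = {k for k, v in scores.items() if v <= cut}
    if not above or not below:
        raise ValueError(f"cutoff {cut:.4g} leaves one side empty")
    return above, below, cut


def step5_split_merged_bin(
    bin_scaffolds: list[ScaffoldRecord],
    scg_dup_scaffolds: set[str],
    external_model: MotifModel,
    cutoff: float | str = "auto",
    pseudocount: float = 1.0,
    per_window: bool = True,
) -> tuple[dict[str, str], float, tuple[set[str], set[str]]]:
    """Split a merged bin in two using its duplicate-marker scaffolds.

    Each duplicate-SCG scaffold is scored against an external component's
    model (``per_window=True`` divides by the number of scored windows so
    scaffolds of different length are comparable; a raw-score numeric cutoff
    like the classic -1350 needs ``per_window=False``). The two seed groups
    train one model each, and every scaffold of the bin is classified between
    them. Returns (scaffold -> '1'|'2', cutoff used, seed groups).
    """
    ids = {r.id for r in bin_scaffolds}
    if not scg_dup_scaffolds <= ids:
        raise ValueError("duplicate-SCG scaffolds must belong to the bin")
    if len(scg_dup_scaffolds) < 2:
        raise ValueError("need >= 2 duplicate-SCG scaffolds to seed a split")
    by_id = {r.id: r for r in bin_scaffolds}
    scores: dict[str, float] = {}
    for sid in sorted(scg_dup_scaffolds):
        seq = by_id[sid].seq
        lp = nb_log_posterior(external_model, seq)
        scores[sid] = lp / max(len(seq) - 3, 1) if per_window else lp
    above, below, cut = split_scores_at_cutoff(scores, cutoff)
    model_a = train_nb_model([by_id[s].seq for s in sorted(above)], "1", pseudocount)
    model_b = train_nb_model([by_id[s].seq for s in sorted(below)], "2", pseudocount)
    sides = {r.id: nb_classify([model_a, model_b], r.seq).best_label for r in bin_scaffolds}
    return sides, cut, (above, below)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    scaffolds: list[ScaffoldRecord],
    hits: list[AlignmentHit],
    depth_table: Mapping[str, np.ndarray],
    scg_hits: list[SCGHit],
    config: PipelineConfig,
) -> PipelineResult:
    """Run steps 1-5 end to end; deterministic for fixed inputs."""
    if not scaffolds:
        raise ValueError("empty scaffold set")
    kept = [r for r in scaffolds if r.length >= config.min_scaffold_len]
    excluded = sorted(r.id for r in scaffolds if r.length < config.min_scaffold_len)
    seqs = {r.id: r.seq for r in kept}
    lengths = {r.id: r.length for r in kept}

    summaries: dict[str, CoverageSummary] = {}
    for r in kept:
        if r.id not in depth_table:
            raise ValueError(f"scaffold {r.id!r} has no depth data")
        summaries[r.id] = scaffold_mean_coverage(depth_table[r.id], config.trim, r.id)

    af_records = af_table([h for h in hits if h.qry_id in lengths], lengths, config.min_hit_len)
    isolate_labels = {h.ref_id for h in hits}
    for iso in sorted(isolate_labels):
        if not any(r.isolate_label == iso for r in af_records):
            log.warning("isolate %s has zero usable alignments", iso)

    assignments, conflicts, low_af = step2_assign_isolates(af_records, config.af_threshold)
    assignments = {s: a for s, a in assignments.items() if s in seqs}
    low_af = {s for s in low_af if s in seqs}

    # component ranges: config-supplied, isolates inferred from step 2 if absent
    ranges: dict[str, CoverageRange] = dict(config.ranges)
    from .coverage import infer_coverage_range  # local to avoid cycle at import
    for iso in sorted(isolate_labels):
        if iso not in ranges:
            iso_sum = [summaries[s] for s, a in assignments.items() if a.label == iso]
            if iso_sum:
                ranges[iso] = infer_coverage_range(iso_sum, iso, outlier_policy="auto")
    if not ranges:
        raise ValueError("no coverage ranges available (config empty and no isolate priming)")

    unaligned = sorted(set(seqs) - set(assignments) - low_af)
    step3_asn, deferred3, pending = step3_assign_unaligned(
        unaligned, summaries, ranges, None, seqs)
    assignments.update(step3_asn)

    # train all component models on the primary MAGs
    train_sets: dict[str, list[str]] = {}
    for s, a in assignments.items():
        train_sets.setdefault(a.label, []).append(seqs[s])
    models: dict[str, MotifModel] = {}
    for lab in sorted(ranges):
        if lab in train_sets:
            models[lab] = train_nb_model(train_sets[lab], lab, config.pseudocount,
                                         config.min_training_bp)
        else:
            log.warning("component %s has no primary scaffolds; no model trained", lab)

    amb_asn, amb_deferred, _ = step3_assign_unaligned(pending, summaries, ranges, models, seqs)
    assignments.update(amb_asn)

    deferred = (deferred3 | amb_deferred | low_af) - set(assignments)
    step4_asn = step4_assign_low_af(deferred, af_records, summaries, ranges, models,
                                    isolate_labels, seqs)
    assignments.update(step4_asn)

    # step 5: detect and split merged bins via SCG duplication
    resolved = resolve_annotations([h for h in scg_hits if h.scaffold_id in seqs])
    bin_map = {s: a.label for s, a in assignments.items()}
    for s in seqs:
        bin_map.setdefault(s, None)
    table = scg_copy_table(resolved, bin_map, config.merge_flag_frac)
    split_info = {}
    external_candidates = sorted(lab for lab in models if lab in isolate_labels) or sorted(models)
    for mag in sorted(table.suspect_merge):
        if not table.suspect_merge[mag]:
            continue
        dup = table.multicopy_scaffolds[mag]
        if len(dup) < 2:
            log.warning("bin %s flagged merged but has %d duplicate-SCG scaffolds; not split",
                        mag, len(dup))
            continue
        external = models[[lab for lab in external_candidates if lab != mag][0]]
        members = [r for r in kept if assignments[r.id].label == mag]
        sides, cut, seeds = step5_split_merged_bin(
            members, dup, external, config.posterior_cutoff,
            config.pseudocount, config.step5_per_window)
        for r in members:
            assignments[r.id] = Assignment(f"{mag}.{sides[r.id]}", "step5",
                                           assignments[r.id].detail)
        split_info[mag] = {"cutoff": cut, "n_seed_hi": len(seeds[0]), "n_seed_lo": len(seeds[1])}
        log.info("split merged bin %s at cutoff %.4g", mag, cut)

    # bookkeeping
    assert set(assignments) == set(seqs), "assignment totality violated"
    mags: dict[str, list[str]] = {}
    for s in sorted(assignments):
        mags.setdefault(assignments[s].label, []).append(s)
    step_counts: dict[str, dict[str, int]] = {}
    for s, a in assignments.items():
        d = step_counts.setdefault(a.step_tag, {"n": 0, "bp": 0})
        d["n"] += 1
        d["bp"] += lengths[s]
    report = {
        "n_input": len(scaffolds),
        "n_assigned": len(assignments),
        "n_excluded_short": len(excluded),
        "assigned_bp": sum(lengths.values()),
        "per_step": step_counts,
        "conflicts": conflicts,
        "ranges": {lab: (r.lo, r.hi) for lab, r in ranges.items()},
        "splits": split_info,
    }
    return PipelineResult(assignments, excluded, report, mags, summaries, af_records)
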