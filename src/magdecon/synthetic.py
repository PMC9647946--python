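"""Seeded generator of a toy microbial consortium with the statistical
structure the deconvolution pipeline assumes.

The default world: six genomes of 300 kb, each an order-3 Markov chain with
its own transition matrix drawn from a symmetric Dirichlet(1) (so genomes
carry distinct 4-mer signatures); coverage levels 1000/300/100/40/21/20-fold
spanning the dominant-to-rare spread of a real low-complexity consortium,
with the two rarest genomes deliberately overlapping in coverage (the
merged-bin case the pipeline's final step must split); two genomes isolated
in culture at ~99% assembly completeness; 107 single-copy markers planted
per genome; and ~2% of scaffolds at 10x their genome's depth, emulating
plasmid-like abnormally-high-coverage scaffolds.

Scaffolds are exact genome substrings (assembly error is out of scope;
partial-alignment hits are injected directly instead), and per-base depth is
Poisson around the per-scaffold level, the standard model for shotgun
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coverage import CoverageRange, CoverageSummary, infer_coverage_range, scaffold_mean_coverage
from .formats_io import AlignmentHit, ScaffoldRecord
from .scg_analysis import SCGHit


@dataclass(frozen=True)
class SimConfig:
    n_genomes: int = 6
    genome_size: int = 300_000
    coverage_levels: tuple[float, ...] = (1000, 300, 100, 40, 21, 20)
    isolate_indices: tuple[int, ...] = (1, 2)   # genomes at 300x and 100x
    isolate_completeness: float = 0.99
    scaffold_len_median: int = 8_000
    scaffold_len_sigma: float = 0.7
    scaffold_len_min: int = 500
    scaffold_len_max: int = 50_000
    n_scgs: int = 107
    scg_duplicates: int = 0        # extra copies planted per genome
    plasmid_frac: float = 0.02
    plasmid_factor: float = 10.0
    jitter_sigma: float = 0.05
    dirichlet_alpha: float = 1.0
    partial_af_frac: float = 0.1   # retained isolate scaffolds given a 30-89% AF hit
    overlap_pair: tuple[int, int] = (4, 5)  # genomes at 21x and 20x


@dataclass
class TruthSet:
    config: SimConfig
    seed: int
    genome_labels: list[str]
    transition: dict[str, np.ndarray]          # label -> 64x4 row-stochastic
    scaffolds: list[ScaffoldRecord]
    gold: dict[str, str]                       # scaffold -> genome label
    genome_level: dict[str, float]
    scaffold_level: dict[str, float]           # expected depth incl. jitter/plasmid
    scaffold_offset: dict[str, int]            # position within source genome
    plasmid_like: set[str]
    isolate_labels: list[str]
    isolate_retained: dict[str, set[str]]      # isolate -> retained scaffold ids

    def genome_scaffolds(self, label: str) -> list[ScaffoldRecord]:
        return [r for r in self.scaffolds if self.gold[r.id] == label]

    def scaffold_lengths(self) -> dict[str, int]:
        return {r.id: r.length for r in self.scaffolds}


def _markov_sequence(rng: np.random.Generator, trans: np.ndarray, length: int) -> str:
    cum = np.cumsum(trans, axis=1)
    cum[:, -1] = 1.0
    bases = "ACGT"
    u = rng.random(length)
    out = []
    ctx = int(rng.integers(64))
    for i in range(length):
        row = cum[ctx]
        b = int(np.searchsorted(row, u[i], side="right"))
        b = min(b, 3)
        out.append(bases[b])
        ctx = (ctx * 4 + b) % 64
    return "".join(out)


def simulate_consortium(config: SimConfig = SimConfig(), seed: int = 17) -> TruthSet:
    """Generate genomes, scaffolds, isolates and truth labels (deterministic
    for a given seed)."""
    if len(config.coverage_levels) != config.n_genomes:
        raise ValueError("need one coverage level per genome")
    for i in config.isolate_indices:
        if not (0 <= i < config.n_genomes):
            raise ValueError(f"isolate index {i} out of range")
    rng = np.random.default_rng(seed)
    labels = [f"G{i + 1}" for i in range(config.n_genomes)]
    transition: dict[str, np.ndarray] = {}
    scaffolds: list[ScaffoldRecord] = []
    gold: dict[str, str] = {}
    offsets: dict[str, int] = {}
    scaffold_level: dict[str, float] = {}
    plasmid_like: set[str] = set()
    genome_level = {lab: float(lv) for lab, lv in zip(labels, config.coverage_levels)}

    mu = np.log(config.scaffold_len_median)
    for lab in labels:
        trans = rng.dirichlet([config.dirichlet_alpha] * 4, size=64)
        transition[lab] = trans
        genome = _markov_sequence(rng, trans, config.genome_size)
        pos = 0
        idx = 0
        while pos < len(genome):
            draw = int(np.clip(np.exp(rng.normal(mu, config.scaffold_len_sigma)),
                               config.scaffold_len_min, config.scaffold_len_max))
            remaining = len(genome) - pos
            if remaining - draw < config.scaffold_len_min:
                draw = remaining
            sid = f"{lab}_s{idx:03d}"
            scaffolds.append(ScaffoldRecord(sid, genome[pos : pos + draw]))
            gold[sid] = lab
            offsets[sid] = pos
            level = genome_level[lab] * float(np.exp(rng.normal(0.0, config.jitter_sigma)))
            if rng.random() < config.plasmid_frac:
                plasmid_like.add(sid)
                level *= config.plasmid_factor
            scaffold_level[sid] = level
            pos += draw
            idx += 1

    isolate_labels = [labels[i] for i in config.isolate_indices]
    isolate_retained: dict[str, set[str]] = {}
    for lab in isolate_labels:
        ids = [r.id for r in scaffolds if gold[r.id] == lab]
        total = sum(len(r.seq) for r in scaffolds if r.id in set(ids))
        budget = total * (1.0 - config.isolate_completeness)
        order = list(rng.permutation(ids))
        lengths = {r.id: r.length for r in scaffolds}
        dropped_bp = 0
        dropped: set[str] = set()
        for sid in order:
            if dropped_bp + lengths[sid] <= budget:
                dropped.add(sid)
                dropped_bp += lengths[sid]
        if not dropped:
            raise ValueError(
                f"isolate {lab}: completeness {config.isolate_completeness} infeasible "
                "(dropping any scaffold undershoots)"
            )
        isolate_retained[lab] = set(ids) - dropped

    return TruthSet(config, seed, labels, transition, scaffolds, gold, genome_level,
                    scaffold_level, offsets, plasmid_like, isolate_labels, isolate_retained)


def simulate_depth(truth: TruthSet, seed: int | None = None) -> dict[str, np.ndarray]:
    """Per-base Poisson depth around each scaffold's expected level."""
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    table: dict[str, np.ndarray] = {}
    for rec in truth.scaffolds:
        level = truth.scaffold_level[rec.id]
        depths = rng.poisson(level, size=rec.length).astype(float)
        table[rec.id] = depths
        if rec.length >= 2000:
            mean = depths[100:-100].mean() if rec.length > 200 else depths.mean()
            tol = 5.0 * np.sqrt(level / rec.length) + 1e-9
            assert abs(mean - level) < max(tol, 0.02 * level), (
                f"{rec.id}: depth mean {mean:.1f} implausibly far from level {level:.1f}"
            )
    return table


def emit_alignments_and_scgs(
    truth: TruthSet,
) -> tuple[list[AlignmentHit], list[SCGHit], dict[str, str]]:
    """Emit the tabular by-products a real run would get from the aligner and
    marker search: one full-length hit per retained isolate scaffold (a
    seeded fraction replaced by 30-89% partial hits, exercising the low-AF
    path), one planted gene per (scaffold, SCG), and the gold standard."""
    rng = np.random.default_rng(truth.seed + 2)
    cfg = truth.config
    lengths = truth.scaffold_lengths()
    hits: list[AlignmentHit] = []
    for iso in truth.isolate_labels:
        for sid in sorted(truth.isolate_retained[iso]):
            L = lengths[sid]
            off = truth.scaffold_offset[sid]
            partial = rng.random() < cfg.partial_af_frac and L >= 1000
            if partial:
                frac = rng.uniform(0.30, 0.89)
                hit_len = max(200, int(L * frac))
                start = int(rng.integers(1, L - hit_len + 2))
                hits.append(AlignmentHit(iso, sid, start, start + hit_len - 1,
                                         off + start, off + start + hit_len - 1, 99.9))
            else:
                hits.append(AlignmentHit(iso, sid, 1, L, off + 1, off + L, 100.0))

    scg_hits: list[SCGHit] = []
    for lab in truth.genome_labels:
        scafs = sorted(sid for sid, g in truth.gold.items() if g == lab)
        for k in range(cfg.n_scgs):
            sid = scafs[k % len(scafs)]
            scg_hits.append(SCGHit(f"{sid}_gene{k:03d}", sid, f"SCG{k + 1:03d}", 1e-30))
        for k in range(cfg.scg_duplicates):
            sid = scafs[int(rng.integers(len(scafs)))]
            scg_hits.append(SCGHit(f"{sid}_dup{k:03d}", sid, f"SCG{k + 1:03d}", 1e-30))
    return hits, scg_hits, dict(truth.gold)


def isolate_records(truth: TruthSet, label: str) -> list[ScaffoldRecord]:
    """The isolate assembly: the source genome minus its dropped scaffolds."""
    return [r for r in truth.scaffolds if r.id in truth.isolate_retained[label]]


def component_range_plan(
    truth: TruthSet,
    summaries: dict[str, CoverageSummary],
) -> dict[str, CoverageRange]:
    """Coverage ranges for every pipeline component, inferred from the
    truth-labelled scaffold subsets (the 'inference on labeled subsets' route;
    a real run derives these from coverage peaks plus manual curation).

    The overlapping pair is one merged component until the SCG-duplication
    step splits it. Known abnormally-high-coverage (plasmid-like) scaffolds
    are excluded from range determination via the explicit-list policy, the
    manual-curation route; the automatic >10x-median rule can miss a 10x
    outlier that jittered slightly low.
    """
    cfg = truth.config
    pair = {truth.genome_labels[i] for i in cfg.overlap_pair}
    plan: dict[str, CoverageRange] = {}
    groups: dict[str, list[str]] = {}
    for lab in truth.genome_labels:
        comp = "+".join(sorted(pair)) if lab in pair else lab
        groups.setdefault(comp, []).append(lab)
    for comp, labs in groups.items():
        subset = [summaries[r.id] for r in truth.scaffolds if truth.gold[r.id] in labs]
        plan[comp] = infer_coverage_range(subset, comp, outlier_policy="explicit",
                                          exclude_ids=tuple(sorted(truth.plasmid_like)))
    return plan
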