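import numpy as np
import pytest

import magdecon as m
from magdecon.coverage import scaffold_mean_coverage


@pytest.fixture(scope="session")
def truth():
    """The reference synthetic consortium: 6 genomes, 2 isolates, one
    coverage-overlapping pair, seed 17."""
    return m.simulate_consortium(m.SimConfig(), seed=17)


@pytest.fixture(scope="session")
def depth_table(truth):
    return m.simulate_depth(truth)


@pytest.fixture(scope="session")
def tabular(truth):
    hits, scg_hits, gold = m.emit_alignments_and_scgs(truth)
    return {"hits": hits, "scg_hits": scg_hits, "gold": gold}


@pytest.fixture(scope="session")
def summaries(truth, depth_table):
    return {r.id: scaffold_mean_coverage(depth_table[r.id], 100, r.id)
            for r in truth.scaffolds}


@pytest.fixture(scope="session")
def pipeline_result(truth, depth_table, tabular, summaries):
    """One shared end-to-end run of the five-step pipeline on the reference
    consortium."""
    cfg = m.PipelineConfig(ranges=m.component_range_plan(truth, summaries))
    return m.run_pipeline(truth.scaffolds, tabular["hits"], depth_table,
                          tabular["scg_hits"], cfg)


@pytest.fixture(scope="session")
def markov_pair():
    """Two seeded order-3 Markov genomes (200 kb each) with their trained
    models, for classifier-accuracy checks."""
    rng = np.random.default_rng(7)
    genomes = {}
    for lab in ("A", "B"):
        trans = rng.dirichlet([1.0] * 4, size=64)
        genomes[lab] = m.synthetic._markov_sequence(rng, trans, 200_000)
    models = {lab: m.train_nb_model([seq], lab) for lab, seq in genomes.items()}
    return genomes, models
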