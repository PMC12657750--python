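import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")

from dipaseq import (
    SimConfig,
    build_dipa_table,
    filter_genes,
    make_design,
    normalize_log2,
    simulate_counts,
    size_factors,
    test_contrast,
)


def run_single_stage_pipeline(cfg: SimConfig, stage: str = "S1"):
    """Simulate one stage and return (dipa_table, truth, contrasts)."""
    design = make_design([stage], n_per_group=cfg.n_per_group)
    counts, truth = simulate_counts(design, cfg)
    kept = filter_genes(counts)
    em = normalize_log2(kept, size_factors(kept))
    cx = test_contrast(em, design, "SHAM_VEH", "BDL_VEH", stage=stage)
    cy = test_contrast(em, design, "SHAM_VEH", "BDL_TRT", stage=stage)
    dt = build_dipa_table(cx, cy)
    truth = truth.set_index("gene_id").loc[dt.index]
    return dt, truth, (cx, cy)


@pytest.fixture(scope="session")
def small_design():
    return make_design(n_per_group=5)


@pytest.fixture(scope="session")
def small_simulation(small_design):
    cfg = SimConfig(n_genes=300, seed=11)
    counts, truth = simulate_counts(small_design, cfg)
    return counts, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_counts(rng):
    """A 50-gene x 12-sample negative-binomial matrix for oracle checks."""
    mu = rng.uniform(5, 200, size=(50, 1))
    counts = rng.poisson(rng.gamma(5.0, mu / 5.0, size=(50, 12)))
    return pd.DataFrame(
        counts,
        index=pd.Index([f"g{i}" for i in range(50)], name="gene_id"),
        columns=[f"s{j}" for j in range(12)],
    )
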