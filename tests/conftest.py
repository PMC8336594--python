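import numpy as np
import pytest

import spenhance as sp


@pytest.fixture(scope="session")
def tiny_sim():
    """Small paired dataset for fast end-to-end tests."""
    cfg = sp.SimConfig(
        n_populations=3, cells_spatial=40, cells_reference=60,
        genes_shared=12, genes_unique_pool=80, seed=7,
    )
    return sp.simulate_pair(cfg)


@pytest.fixture(scope="session")
def tiny_pair(tiny_sim):
    pair, merged = sp.prepare_pair(
        tiny_sim.spatial_counts, tiny_sim.reference_counts,
        n_top_hvg=50, min_cells=3, seed=7,
    )
    return pair, merged


@pytest.fixture(scope="session")
def recovery_experiment():
    """Gene-split cross-validation on the generator's default conditions.

    Shared by the parameter-recovery and clustering-improvement checks;
    trained once per session with a reduced epoch budget to keep the
    runtime of the suite reasonable.
    """
    sim = sp.simulate_pair(sp.SimConfig(seed=0))
    pair, _ = sp.prepare_pair(sim.spatial_counts, sim.reference_counts, seed=0)
    cfg = sp.ModelConfig(epochs=30, batch_size=256, seed=0)
    pred = sp.run_cv(pair, folds=5, seed=0, cfg=cfg)
    return {"sim": sim, "pair": pair, "pred": pred}


def random_expression(rng: np.random.Generator, n_genes=6, n_cells=5, state="raw_counts"):
    vals = rng.integers(0, 20, size=(n_genes, n_cells)).astype(float)
    vals[0, 0] = max(vals[0, 0], 1.0)  # keep first cell non-empty
    return sp.ExpressionMatrix(
        vals,
        [f"g{i}" for i in range(n_genes)],
        [f"c{j}" for j in range(n_cells)],
        state,
    )
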