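"""Synthetic paired spatial / reference datasets with known ground truth.

The generator emulates the statistical structure the enhancement method
assumes: a spatial panel and a scRNA-seq reference profiled from the
same tissue, sharing cell populations and a small gene panel, with the
reference carrying a large additional gene set and both datasets
suffering dataset-specific dropout.

Counts are negative-binomial around population×gene means drawn from a
log-normal, with independent Bernoulli dropout per entry.  Dropout is
expression-dependent — the per-entry dropout probability falls with the
underlying mean on a logistic curve, calibrated so that the average
probability equals the nominal dropout rate — because in real data
sparsity concentrates in weakly expressed genes while strong markers
are reliably detected.  Population sizes are unbalanced (one dominant
population), as is typical of real tissue.  The noise-free population
log-means are kept as the oracle for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import RAW_COUNTS, ExpressionMatrix


@dataclass
class SimConfig:
    """Generator settings.

    ``mean_log_loc`` / ``mean_log_scale`` parameterize the log-normal
    from which population×gene mean counts are drawn; their defaults
    keep typical means high enough that realized sparsity is governed
    by the dropout probabilities rather than by sampling zeros.
    ``count_dispersion`` is the negative-binomial size parameter
    (smaller = noisier counts).
    """

    n_populations: int = 3
    cells_spatial: int = 300
    cells_reference: int = 500
    genes_shared: int = 30
    genes_unique_pool: int = 3000
    mean_log_loc: float = 2.0
    mean_log_scale: float = 1.0
    dropout_spatial: float = 0.6
    dropout_reference: float = 0.8
    count_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_spatial", "dropout_reference"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {p}")
        for name in (
            "n_populations", "cells_spatial", "cells_reference",
            "genes_shared", "genes_unique_pool",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be positive")


@dataclass
class SimOutput:
    spatial_counts: ExpressionMatrix
    reference_counts: ExpressionMatrix
    truth_log_means: np.ndarray  # populations × genes, log1p of the mean counts
    gene_names: list[str]
    labels_spatial: dict[str, str]
    labels_reference: dict[str, str]
    config: SimConfig


def _population_proportions(n: int) -> np.ndarray:
    """Unbalanced proportions with one dominant population (halving sizes)."""
    w = 0.5 ** np.arange(n)
    return w / w.sum()


def _dropout_probabilities(
    mu: np.ndarray, rate: float, shape: float = 1.0
) -> np.ndarray:
    """Per-entry dropout probabilities, decreasing in the mean.

    Logistic in log-mean, ``p = 1 / (1 + exp((log mu - x0) / shape))``,
    with the midpoint ``x0`` solved by bisection so the mean probability
    equals ``rate``.  Entries with higher expected expression are less
    likely to drop out, as in real data.
    """
    if rate <= 0.0:
        return np.zeros_like(mu)
    if rate >= 1.0:
        return np.ones_like(mu)
    logmu = np.log(np.maximum(mu, 1e-12))
    lo, hi = logmu.min() - 50 * shape, logmu.max() + 50 * shape
    for _ in range(100):
        x0 = (lo + hi) / 2
        mean_p = float(np.mean(1.0 / (1.0 + np.exp((logmu - x0) / shape))))
        if mean_p < rate:
            lo = x0
        else:
            hi = x0
    return 1.0 / (1.0 + np.exp((logmu - (lo + hi) / 2) / shape))


def _draw_counts(
    rng: np.random.Generator,
    means: np.ndarray,
    pops: np.ndarray,
    dispersion: float,
    dropout: float,
) -> np.ndarray:
    """Genes × cells negative-binomial counts with Bernoulli dropout."""
    mu = means[pops].T  # genes × cells
    p = dispersion / (dispersion + mu)
    raw = rng.negative_binomial(dispersion, p).astype(float)
    counts = raw.copy()
    if dropout > 0:
        counts[rng.random(counts.shape) < _dropout_probabilities(mu, dropout)] = 0.0
    # a measured cell always has some signal: restore the strongest entry
    # of any cell emptied by dropout (or of the mean profile if raw is empty)
    empty = np.flatnonzero(counts.sum(axis=0) == 0)
    for j in empty:
        g = int(np.argmax(raw[:, j]))
        counts[g, j] = raw[g, j] if raw[g, j] > 0 else 1.0
    return counts


def simulate_pair(cfg: SimConfig | None = None) -> SimOutput:
    """Generate one paired dataset; identical seeds give identical output."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n_genes = cfg.genes_shared + cfg.genes_unique_pool
    genes = [f"g{i:05d}" for i in range(n_genes)]
    shared = genes[: cfg.genes_shared]

    means = rng.lognormal(
        cfg.mean_log_loc, cfg.mean_log_scale, (cfg.n_populations, n_genes)
    )
    props = _population_proportions(cfg.n_populations)
    pops_spatial = rng.choice(cfg.n_populations, size=cfg.cells_spatial, p=props)
    pops_reference = rng.choice(cfg.n_populations, size=cfg.cells_reference, p=props)

    sp_counts = _draw_counts(
        rng, means[:, : cfg.genes_shared], pops_spatial,
        cfg.count_dispersion, cfg.dropout_spatial,
    )
    ref_counts = _draw_counts(
        rng, means, pops_reference, cfg.count_dispersion, cfg.dropout_reference
    )

    sp_cells = [f"sp{i:05d}" for i in range(cfg.cells_spatial)]
    ref_cells = [f"rc{i:05d}" for i in range(cfg.cells_reference)]
    return SimOutput(
        spatial_counts=ExpressionMatrix(sp_counts, shared, sp_cells, RAW_COUNTS),
        reference_counts=ExpressionMatrix(ref_counts, genes, ref_cells, RAW_COUNTS),
        truth_log_means=np.log1p(means),
        gene_names=genes,
        labels_spatial={c: f"pop{p}" for c, p in zip(sp_cells, pops_spatial)},
        labels_reference={c: f"pop{p}" for c, p in zip(ref_cells, pops_reference)},
        config=cfg,
    )


def ground_truth_expression(
    sim: SimOutput, genes: list[str], cells: list[str]
) -> np.ndarray:
    """Noise-free log-mean expression, |genes| × |cells|.

    Rows are population log-means for each cell's population — the
    dropout-free oracle against which predictions are scored.
    """
    gene_index = {g: i for i, g in enumerate(sim.gene_names)}
    missing = [g for g in genes if g not in gene_index]
    if missing:
        raise KeyError(f"unknown genes: {missing[:10]}")
    labels = {**sim.labels_spatial, **sim.labels_reference}
    missing_c = [c for c in cells if c not in labels]
    if missing_c:
        raise KeyError(f"unknown cells: {missing_c[:10]}")
    pop_of = {f"pop{p}": p for p in range(sim.config.n_populations)}
    gi = [gene_index[g] for g in genes]
    ci = [pop_of[labels[c]] for c in cells]
    return sim.truth_log_means[np.ix_(ci, gi)].T
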