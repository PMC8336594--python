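"""Weighted k-nearest-neighbor prediction over the joint embedding.

Each spatial cell's unmeasured expression is predicted as a convex
combination of its nearest reference cells in the latent space:
cosine distances select the 50 nearest reference cells, neighbors with
non-positive cosine similarity are dropped, the remaining K neighbors
get weights

    w_ik = (1 - d_ik / sum_k d_ik) / (K - 1)

which sum to one, and the prediction is Y_i = sum_k w_ik X_k with X_k
the neighbor's reference expression of the genes to predict.
Predictions are averaged over the retained model snapshots, and a
gene-split cross-validation treats each fold of the shared genes as
unmeasured in turn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autoencoder import ModelConfig, TrainedModel, embed, fit
from .matrix import NORMALIZED_LOG, ExpressionMatrix
from .preprocess import PairedDataset, build_merged


@dataclass
class NeighborSet:
    """Retained reference neighbors of one spatial cell."""

    spatial_cell_id: str
    neighbor_indices: np.ndarray
    distances: np.ndarray
    weights: np.ndarray
    fallback: bool = False  # all candidates had non-positive similarity


@dataclass
class PredictionResult:
    """Predicted genes × spatial-cells expression on the reference log scale."""

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    n_snapshots_averaged: int

    def to_expression_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(
            self.values, list(self.gene_names), list(self.cell_ids), NORMALIZED_LOG
        )


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cos(a, b); a zero-norm vector has similarity 0 by convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0
    return float(1.0 - (a @ b) / (na * nb))


def cosine_distance_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances between rows of ``a`` and rows of ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    an = np.divide(a, na, out=np.zeros_like(a), where=na > 0)
    bn = np.divide(b, nb, out=np.zeros_like(b), where=nb > 0)
    return 1.0 - an @ bn.T


def compute_weights(distances: np.ndarray, k: int | None = None) -> np.ndarray:
    """Weights for K retained neighbors from their cosine distances.

    K = 1 degenerates to weight 1; all-equal distances (including all
    zero) give exactly 1/K each.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("distances must be a non-empty 1-D array")
    if np.any(d < 0):
        raise ValueError("negative distance")
    kk = d.size if k is None else k
    if kk != d.size:
        raise ValueError(f"K={kk} does not match {d.size} distances")
    if kk == 1:
        return np.array([1.0])
    if np.all(d == d[0]):
        return np.full(kk, 1.0 / kk)
    return (1.0 - d / d.sum()) / (kk - 1)


def select_neighbors(
    embed_spatial: np.ndarray,
    embed_reference: np.ndarray,
    k: int = 50,
    spatial_cell_ids: list[str] | None = None,
) -> list[NeighborSet]:
    """For each spatial cell, the k nearest reference cells by cosine distance.

    Candidates with non-positive cosine similarity (distance >= 1) are
    filtered out; if none survive, the original k candidates are kept
    with uniform weights.  Distance ties break toward the smaller
    reference index (stable sort).
    """
    mr = embed_reference.shape[0]
    if k > mr:
        raise ValueError(f"k={k} exceeds number of reference cells ({mr})")
    dist = cosine_distance_matrix(embed_spatial, embed_reference)
    ids = spatial_cell_ids or [str(i) for i in range(embed_spatial.shape[0])]
    out = []
    for i in range(dist.shape[0]):
        order = np.argsort(dist[i], kind="stable")[:k]
        d = dist[i, order]
        keep = d < 1.0
        if keep.any():
            nbr, dd, fb = order[keep], d[keep], False
            w = compute_weights(dd)
        else:
            nbr, dd, fb = order, d, True
            w = np.full(k, 1.0 / k)
        out.append(NeighborSet(ids[i], nbr, dd, w, fallback=fb))
    return out


def predict_cell(
    neighbors: NeighborSet, ref_expr: ExpressionMatrix, genes: list[str]
) -> np.ndarray:
    """Weighted neighbor average of the reference expression of ``genes``."""
    index = {g: j for j, g in enumerate(ref_expr.gene_names)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise KeyError(f"genes not in reference: {missing[:10]}")
    rows = [index[g] for g in genes]
    x = ref_expr.values[np.ix_(rows, neighbors.neighbor_indices)]
    return x @ neighbors.weights


def predict_ensemble(
    model: TrainedModel,
    spatial_input: np.ndarray,
    reference_input: np.ndarray,
    ref_expr: ExpressionMatrix,
    genes: list[str],
    spatial_cell_ids: list[str],
    k: int = 50,
) -> PredictionResult:
    """Average the weighted k-NN prediction over the model snapshots.

    ``spatial_input`` and ``reference_input`` are cells × (S∪U) matrices
    in the training gene order, spatial cells zero-padded over U.
    """
    if not model.snapshots:
        raise ValueError("model has no snapshots")
    index = {g: j for j, g in enumerate(ref_expr.gene_names)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise KeyError(f"genes not in reference: {missing[:10]}")
    rows = np.array([index[g] for g in genes])
    expr = ref_expr.values[rows]

    acc = np.zeros((len(genes), spatial_input.shape[0]))
    for snap in model.snapshots:
        et = embed(snap, spatial_input)
        er = embed(snap, reference_input)
        for i, nbr in enumerate(select_neighbors(et, er, k, spatial_cell_ids)):
            acc[:, i] += expr[:, nbr.neighbor_indices] @ nbr.weights
    acc /= len(model.snapshots)
    return PredictionResult(
        values=acc,
        gene_names=list(genes),
        cell_ids=list(spatial_cell_ids),
        n_snapshots_averaged=len(model.snapshots),
    )


def _model_inputs(
    pair: PairedDataset, gene_order: list[str], n_shared: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cells × (S∪U) inputs for both origins, spatial zero-padded over U."""
    shared = gene_order[:n_shared]
    sp = np.zeros((pair.spatial.n_cells, len(gene_order)))
    sp[:, :n_shared] = pair.spatial.subset_genes(shared).values.T
    rf = pair.reference.subset_genes(gene_order).values.T
    return sp, rf


def enhance(
    pair: PairedDataset,
    genes: list[str] | None = None,
    cfg: ModelConfig | None = None,
    k: int = 50,
    seed: int = 0,
) -> tuple[PredictionResult, TrainedModel]:
    """Train on the full paired dataset and predict ``genes``.

    With ``genes`` omitted, all reference-unique HVG genes U are
    predicted.
    """
    cfg = cfg or ModelConfig()
    if genes is None:
        genes = list(pair.unique_genes)
    _, merged = build_merged(pair.spatial, pair.reference, pair.unique_genes, seed)
    model = fit(merged, cfg)
    sp, rf = _model_inputs(pair, merged.gene_order, merged.n_shared)
    pred = predict_ensemble(
        model, sp, rf, pair.reference, genes, list(pair.spatial.cell_ids), k
    )
    return pred, model


def assign_folds(genes: list[str], folds: int, seed: int) -> list[list[str]]:
    """Seeded balanced partition of genes into contiguous shuffled chunks.

    Larger folds come first when the split is uneven.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(genes) < folds:
        raise ValueError(f"{len(genes)} genes cannot form {folds} folds")
    perm = np.random.default_rng(seed).permutation(len(genes))
    chunks = np.array_split(perm, folds)
    return [[genes[i] for i in chunk] for chunk in chunks]


def run_cv(
    pair: PairedDataset,
    folds: int = 5,
    seed: int = 0,
    cfg: ModelConfig | None = None,
    k: int = 50,
) -> PredictionResult:
    """Gene-split cross-validation over the shared genes.

    Each fold's genes are removed from the spatial matrix (treated as
    unmeasured), a model is trained on the remaining shared genes plus
    U, and the held-out genes are predicted; the folds' predictions are
    reassembled so every shared gene is predicted exactly once.  The
    unique gene set U is fixed across folds.
    """
    cfg = cfg or ModelConfig()
    fold_genes = assign_folds(list(pair.shared_genes), folds, seed)
    gene_pos = {g: i for i, g in enumerate(pair.shared_genes)}
    values = np.zeros((pair.n_shared, pair.n_spatial_cells))
    n_snaps = 0
    for f, held_out in enumerate(fold_genes):
        train_genes = [g for g in pair.shared_genes if g not in set(held_out)]
        spatial_f = pair.spatial.subset_genes(train_genes)
        pair_f, merged_f = build_merged(
            spatial_f, pair.reference, pair.unique_genes, seed=seed + f
        )
        cfg_f = ModelConfig(
            latent_dim=cfg.latent_dim, epochs=cfg.epochs,
            batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
            seed=cfg.seed + f, n_snapshots=cfg.n_snapshots,
        )
        model = fit(merged_f, cfg_f)
        sp, rf = _model_inputs(pair_f, merged_f.gene_order, merged_f.n_shared)
        pred = predict_ensemble(
            model, sp, rf, pair.reference, held_out,
            list(pair_f.spatial.cell_ids), k,
        )
        n_snaps = pred.n_snapshots_averaged
        for row, g in enumerate(held_out):
            values[gene_pos[g]] = pred.values[row]
    return PredictionResult(
        values=values,
        gene_names=list(pair.shared_genes),
        cell_ids=list(pair.spatial.cell_ids),
        n_snapshots_averaged=n_snaps,
    )


def baseline_population_mean(
    ref_expr: ExpressionMatrix, genes: list[str], cell_ids: list[str]
) -> PredictionResult:
    """Constant per-gene baseline: every cell gets the reference mean.

    Used as the comparison point for parameter-recovery checks; its
    gene-wise rank correlations are undefined (constant predictions).
    """
    index = {g: j for j, g in enumerate(ref_expr.gene_names)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise KeyError(f"genes not in reference: {missing[:10]}")
    means = ref_expr.values[[index[g] for g in genes]].mean(axis=1)
    return PredictionResult(
        values=np.tile(means[:, None], (1, len(cell_ids))),
        gene_names=list(genes),
        cell_ids=list(cell_ids),
        n_snapshots_averaged=0,
    )
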