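"""Evaluation of predicted spatial expression.

Two complementary views, both computed against the measured spatial
profile and ground-truth population labels:

* Spearman rank correlation per gene (over cells) and per cell (over
  genes) between predicted and measured expression.
* A clustering-based protocol: both the predicted and the measured
  matrix are clustered with the same pipeline (PCA, k-nearest-neighbor
  graph, Louvain community detection with the resolution parameter
  binary-searched so the cluster count matches the number of
  ground-truth populations) and scored with AMI, ARI, NMI and
  homogeneity.  AMI is the headline metric when population sizes are
  unbalanced, which is typical of spatial data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, asdict

import igraph
import numpy as np
from scipy.stats import spearmanr
from sklearn.decomposition import PCA
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    homogeneity_score,
    normalized_mutual_info_score,
)
from sklearn.neighbors import NearestNeighbors

from .knn import PredictionResult
from .matrix import ExpressionMatrix


@dataclass
class Partition:
    """A clustering of cells: one integer/str label per cell."""

    cell_ids: list[str]
    labels: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()))


@dataclass
class ClusteringScores:
    ami: float
    ari: float
    nmi: float
    homo: float


@dataclass
class EvaluationReport:
    gene_spearman: np.ndarray
    cell_spearman: np.ndarray
    predicted: ClusteringScores
    measured: ClusteringScores

    def summary(self) -> dict:
        gs = self.gene_spearman[np.isfinite(self.gene_spearman)]
        cs = self.cell_spearman[np.isfinite(self.cell_spearman)]
        return {
            "median_gene_spearman": float(np.median(gs)) if gs.size else None,
            "median_cell_spearman": float(np.median(cs)) if cs.size else None,
            "n_genes_undefined": int(np.sum(~np.isfinite(self.gene_spearman))),
            "n_cells_undefined": int(np.sum(~np.isfinite(self.cell_spearman))),
            "predicted": asdict(self.predicted),
            "measured": asdict(self.measured),
        }


def spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (the undefined marker) when either vector is constant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    return float(spearmanr(a, b).statistic)


def _aligned(pred: PredictionResult, measured: ExpressionMatrix) -> np.ndarray:
    if list(pred.cell_ids) != list(measured.cell_ids):
        raise ValueError("cell ids of prediction and measured matrix differ")
    if set(pred.gene_names) - set(measured.gene_names):
        raise ValueError("prediction contains genes absent from the measured matrix")
    return measured.subset_genes(list(pred.gene_names)).values


def spearman_genewise(
    pred: PredictionResult, measured: ExpressionMatrix
) -> np.ndarray:
    """One coefficient per gene, over cells; NaN where undefined."""
    m = _aligned(pred, measured)
    return np.array([spearman(pred.values[i], m[i]) for i in range(m.shape[0])])


def spearman_cellwise(
    pred: PredictionResult, measured: ExpressionMatrix
) -> np.ndarray:
    """One coefficient per cell, over genes; NaN where undefined."""
    m = _aligned(pred, measured)
    return np.array(
        [spearman(pred.values[:, j], m[:, j]) for j in range(m.shape[1])]
    )


# ---------------------------------------------------------------------------
# clustering metrics
# ---------------------------------------------------------------------------

def _as_labels(p) -> np.ndarray:
    if isinstance(p, Partition):
        return np.asarray(p.labels)
    return np.asarray(p)


def _check_pair(p: np.ndarray, t: np.ndarray) -> None:
    if p.shape != t.shape:
        raise ValueError(f"partitions differ in length: {p.shape} vs {t.shape}")


def ari(p, t) -> float:
    """Adjusted Rand index between predicted clusters and true labels."""
    p, t = _as_labels(p), _as_labels(t)
    _check_pair(p, t)
    if p.size < 2:
        raise ValueError("ARI needs at least two cells")
    return float(adjusted_rand_score(t, p))


def nmi(p, t) -> float:
    """Mutual information normalized by the geometric mean of the entropies."""
    p, t = _as_labels(p), _as_labels(t)
    _check_pair(p, t)
    if len(set(t.tolist())) < 2:
        raise ValueError("NMI undefined for single-label ground truth")
    return float(normalized_mutual_info_score(t, p, average_method="geometric"))


def ami(p, t) -> float:
    """Mutual information adjusted for chance (arithmetic-mean normalizer)."""
    p, t = _as_labels(p), _as_labels(t)
    _check_pair(p, t)
    if len(set(t.tolist())) < 2:
        raise ValueError("AMI undefined for single-label ground truth")
    return float(adjusted_mutual_info_score(t, p, average_method="arithmetic"))


def homogeneity(p, t) -> float:
    """1 - H(T|P)/H(T): 1 iff every cluster holds a single true population.

    A single-label ground truth has H(T) = 0 and scores 1 by convention.
    """
    p, t = _as_labels(p), _as_labels(t)
    _check_pair(p, t)
    return float(homogeneity_score(t, p))


# ---------------------------------------------------------------------------
# Louvain clustering with resolution search
# ---------------------------------------------------------------------------

def _louvain(graph: igraph.Graph, resolution: float, seed: int) -> np.ndarray:
    igraph.set_random_number_generator(random.Random(seed))
    part = graph.community_multilevel(resolution=resolution)
    return np.asarray(part.membership)


def cluster_with_target_k(
    expr: np.ndarray,
    target_k: int,
    seed: int = 0,
    cell_ids: list[str] | None = None,
    n_pcs: int = 50,
    n_neighbors: int = 15,
    resolution_lo: float = 0.01,
    resolution_hi: float = 10.0,
    max_iter: int = 50,
    hi_cap: float = 100.0,
) -> Partition:
    """Louvain clustering tuned to approximately ``target_k`` clusters.

    ``expr`` is cells × genes.  Pipeline: PCA to at most ``n_pcs``
    components, a ``n_neighbors``-nearest-neighbor graph (Euclidean in
    PC space), then Louvain community detection whose resolution is
    binary-searched; the partition whose cluster count is closest to
    ``target_k`` is returned, preferring fewer clusters on ties.
    """
    expr = np.asarray(expr, dtype=float)
    n_cells = expr.shape[0]
    if n_cells <= n_neighbors:
        raise ValueError(
            f"{n_cells} cells is too few for a {n_neighbors}-neighbor graph"
        )
    if target_k < 1 or target_k > n_cells:
        raise ValueError(f"target_k={target_k} out of range")

    n_comp = int(min(n_pcs, n_cells - 1, expr.shape[1]))
    coords = PCA(n_components=n_comp, svd_solver="full").fit_transform(expr)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = {
        (min(i, j), max(i, j))
        for i in range(n_cells)
        for j in idx[i, 1:]
    }
    graph = igraph.Graph(n=n_cells, edges=sorted(edges))

    evaluated: dict[float, np.ndarray] = {}

    def clusters_at(res: float) -> np.ndarray:
        if res not in evaluated:
            evaluated[res] = _louvain(graph, res, seed)
        return evaluated[res]

    lo, hi = resolution_lo, resolution_hi
    while len(set(clusters_at(hi).tolist())) < target_k and hi < hi_cap:
        hi = min(hi * 2, hi_cap)

    def better(res_a: float, res_b: float | None) -> bool:
        # closest cluster count to target_k; ties prefer fewer clusters
        if res_b is None:
            return True
        ka = len(set(clusters_at(res_a).tolist()))
        kb = len(set(clusters_at(res_b).tolist()))
        return (abs(ka - target_k), ka) < (abs(kb - target_k), kb)

    best: float | None = None
    for res in (lo, hi):
        if better(res, best):
            best = res
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        kmid = len(set(clusters_at(mid).tolist()))
        if better(mid, best):
            best = mid
        if kmid == target_k:
            break
        if kmid < target_k:
            lo = mid
        else:
            hi = mid

    labels = clusters_at(best)
    ids = cell_ids or [str(i) for i in range(n_cells)]
    return Partition(cell_ids=list(ids), labels=labels)


def evaluate_all(
    pred: PredictionResult,
    measured: ExpressionMatrix,
    labels: dict[str, str],
    seed: int = 0,
    n_pcs: int = 50,
    n_neighbors: int = 15,
) -> EvaluationReport:
    """Full report: both Spearman axes plus clustering metrics.

    The predicted matrix and the measured matrix (the baseline) are
    clustered by the identical pipeline and seed with target cluster
    count equal to the number of distinct ground-truth labels.
    """
    missing = [c for c in pred.cell_ids if c not in labels]
    if missing:
        raise ValueError(f"cells without labels: {missing[:10]}")
    truth = np.array([labels[c] for c in pred.cell_ids])
    target_k = len(set(truth.tolist()))

    gene_rho = spearman_genewise(pred, measured)
    cell_rho = spearman_cellwise(pred, measured)

    def scores(matrix_cells_by_genes: np.ndarray) -> ClusteringScores:
        part = cluster_with_target_k(
            matrix_cells_by_genes, target_k, seed=seed,
            cell_ids=list(pred.cell_ids), n_pcs=n_pcs, n_neighbors=n_neighbors,
        )
        return ClusteringScores(
            ami=ami(part.labels, truth),
            ari=ari(part.labels, truth),
            nmi=nmi(part.labels, truth),
            homo=homogeneity(part.labels, truth),
        )

    measured_aligned = _aligned(pred, measured)
    return EvaluationReport(
        gene_spearman=gene_rho,
        cell_spearman=cell_rho,
        predicted=scores(pred.values.T),
        measured=scores(measured_aligned.T),
    )
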