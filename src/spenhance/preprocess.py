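"""Normalization, gene filtering, HVG selection and training-set assembly.

The spatial panel and the scRNA-seq reference are normalized per cell
and log-transformed, the reference contributes its top highly variable
genes outside the panel (the "unique" set U), and the two datasets are
merged — spatial cells zero-padded over U — into a single shuffled
training matrix for the joint-embedding model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import NORMALIZED_LOG, RAW_COUNTS, ExpressionMatrix

ORIGIN_SPATIAL = "spatial"
ORIGIN_REFERENCE = "reference"


@dataclass
class PairedDataset:
    """Aligned spatial + reference matrices with the S/U gene partition.

    ``shared_genes`` (S) are the spatial genes also present in the
    reference, in spatial-matrix order; ``unique_genes`` (U) are
    reference-only genes in highly-variable rank order.  ``q_nonzero``
    is the fraction of non-zero entries in the reference submatrix over
    S ∪ U — one minus the reference data sparsity, used to down-weight
    reconstruction errors at reference zeros.
    """

    spatial: ExpressionMatrix
    reference: ExpressionMatrix
    shared_genes: list[str]
    unique_genes: list[str]
    q_nonzero: float

    @property
    def n_shared(self) -> int:
        return len(self.shared_genes)

    @property
    def n_unique(self) -> int:
        return len(self.unique_genes)

    @property
    def n_spatial_cells(self) -> int:
        return self.spatial.n_cells

    @property
    def n_reference_cells(self) -> int:
        return self.reference.n_cells

    def __post_init__(self) -> None:
        overlap = set(self.shared_genes) & set(self.unique_genes)
        if overlap:
            raise ValueError(f"S and U overlap: {sorted(overlap)[:5]}")
        if not 0.0 <= self.q_nonzero <= 1.0:
            raise ValueError(f"q_nonzero outside [0,1]: {self.q_nonzero}")


@dataclass
class MergedTrainingSet:
    """Shuffled cells × (S then U) matrix combining both datasets.

    Spatial rows are exactly zero over the U columns.  ``n_shared`` and
    ``q_nonzero`` are carried along so the training loss can be formed
    without going back to the paired dataset.
    """

    matrix: np.ndarray
    origin: np.ndarray  # per-row tag, ORIGIN_SPATIAL or ORIGIN_REFERENCE
    cell_ids: list[str]
    gene_order: list[str]
    n_shared: int
    q_nonzero: float
    shuffle_seed: int

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.origin):
            raise ValueError("origin length must match row count")
        if self.matrix.shape[1] != len(self.gene_order):
            raise ValueError("gene_order length must match column count")


def filter_reference_genes(
    ref: ExpressionMatrix, min_cells: int = 10
) -> ExpressionMatrix:
    """Drop genes detected (non-zero) in fewer than ``min_cells`` cells."""
    if ref.state != RAW_COUNTS:
        raise ValueError("gene filtering expects raw counts")
    detected = (ref.values > 0).sum(axis=1)
    keep = detected >= min_cells
    if not keep.any():
        raise ValueError(f"no genes detected in >= {min_cells} cells")
    genes = [g for g, k in zip(ref.gene_names, keep) if k]
    return ExpressionMatrix(ref.values[keep], genes, list(ref.cell_ids), RAW_COUNTS)


def _normalize(em: ExpressionMatrix, scale: float) -> ExpressionMatrix:
    totals = em.values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(f"all-zero cell(s): {[em.cell_ids[i] for i in zero[:10]]}")
    out = np.log1p(scale * em.values / totals)
    return ExpressionMatrix(out, list(em.gene_names), list(em.cell_ids), NORMALIZED_LOG)


def normalize_spatial(spatial: ExpressionMatrix) -> ExpressionMatrix:
    """Per-cell total normalization scaled by the median cell total, then log1p."""
    if spatial.state != RAW_COUNTS:
        raise ValueError("normalize_spatial expects raw counts")
    totals = spatial.values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(
            f"all-zero cell(s): {[spatial.cell_ids[i] for i in zero[:10]]}"
        )
    return _normalize(spatial, float(np.median(totals)))


def normalize_reference(
    ref: ExpressionMatrix, scale: float = 1e6
) -> ExpressionMatrix:
    """Counts-per-``scale`` per cell, then log1p (default counts per million)."""
    if ref.state != RAW_COUNTS:
        raise ValueError("normalize_reference expects raw counts")
    return _normalize(ref, float(scale))


def select_hvg_unique(
    ref: ExpressionMatrix,
    spatial_genes: list[str],
    n_top: int = 2000,
    n_bins: int = 20,
) -> list[str]:
    """Rank reference-only genes by binned normalized dispersion.

    Candidates are reference genes absent from the spatial panel.  Each
    gene's dispersion (variance over mean of the normalized values) is
    z-scored within one of ``n_bins`` equal-frequency mean bins, and the
    top ``n_top`` genes by that score are returned; ties at equal score
    break toward the lexicographically smaller name, which makes the
    selection fully deterministic.
    """
    if ref.state != NORMALIZED_LOG:
        raise ValueError("HVG selection expects normalized data")
    panel = set(spatial_genes)
    pool_idx = [i for i, g in enumerate(ref.gene_names) if g not in panel]
    if not pool_idx:
        raise ValueError("no reference genes outside the spatial panel")
    sub = ref.values[pool_idx]
    names = [ref.gene_names[i] for i in pool_idx]
    means = sub.mean(axis=1)
    var = sub.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(means > 0, var / means, 0.0)

    n = len(pool_idx)
    n_bins_eff = max(1, min(n_bins, n))
    # equal-frequency bins over the mean, stable under mean ties
    order = np.lexsort((np.arange(n), means))
    bins = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins_eff)):
        bins[chunk] = b
    z = np.zeros(n)
    for b in range(n_bins_eff):
        mask = bins == b
        d = disp[mask]
        mu, sd = d.mean(), d.std()
        z[mask] = (d - mu) / sd if sd > 0 else 0.0

    ranked = sorted(range(n), key=lambda i: (-z[i], names[i]))
    return [names[i] for i in ranked[: min(n_top, n)]]


def build_merged(
    spatial: ExpressionMatrix,
    ref: ExpressionMatrix,
    unique_genes: list[str],
    seed: int,
) -> tuple[PairedDataset, MergedTrainingSet]:
    """Assemble the paired dataset and the shuffled merged training matrix.

    Shared genes S keep the spatial-matrix order; columns are S then U
    for both origins; spatial rows are zero over U.  Rows are shuffled
    with ``seed`` so mini-batches mix the two origins.
    """
    if spatial.state != NORMALIZED_LOG or ref.state != NORMALIZED_LOG:
        raise ValueError("both matrices must be normalized before merging")
    ref_genes = set(ref.gene_names)
    shared = [g for g in spatial.gene_names if g in ref_genes]
    if not shared:
        raise ValueError("no shared genes between spatial and reference data")

    spatial_s = spatial.subset_genes(shared)
    ref_su = ref.subset_genes(shared + list(unique_genes))
    q = float(np.count_nonzero(ref_su.values) / ref_su.values.size)

    pair = PairedDataset(
        spatial=spatial_s,
        reference=ref,
        shared_genes=shared,
        unique_genes=list(unique_genes),
        q_nonzero=q,
    )

    ns, nu = len(shared), len(unique_genes)
    mt, mr = spatial.n_cells, ref.n_cells
    mat = np.zeros((mt + mr, ns + nu))
    mat[:mt, :ns] = spatial_s.values.T
    mat[mt:] = ref_su.values.T
    origin = np.array([ORIGIN_SPATIAL] * mt + [ORIGIN_REFERENCE] * mr)
    cells = list(spatial.cell_ids) + list(ref.cell_ids)

    perm = np.random.default_rng(seed).permutation(mt + mr)
    merged = MergedTrainingSet(
        matrix=mat[perm],
        origin=origin[perm],
        cell_ids=[cells[i] for i in perm],
        gene_order=shared + list(unique_genes),
        n_shared=ns,
        q_nonzero=q,
        shuffle_seed=seed,
    )
    return pair, merged


def prepare_pair(
    spatial_raw: ExpressionMatrix,
    ref_raw: ExpressionMatrix,
    n_top_hvg: int = 2000,
    min_cells: int = 10,
    ref_scale: float = 1e6,
    seed: int = 0,
) -> tuple[PairedDataset, MergedTrainingSet]:
    """Full preprocessing: filter, normalize, select U, merge."""
    ref_f = filter_reference_genes(ref_raw, min_cells=min_cells)
    ref_n = normalize_reference(ref_f, scale=ref_scale)
    spatial_n = normalize_spatial(spatial_raw)
    unique = select_hvg_unique(ref_n, spatial_n.gene_names, n_top=n_top_hvg)
    return build_merged(spatial_n, ref_n, unique, seed=seed)
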