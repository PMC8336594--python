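"""Expression matrices and on-disk formats.

The canonical in-memory container is a genes-by-cells matrix with named
axes and an explicit state flag distinguishing raw counts from
normalized log-scale values.  Dense matrices travel as TSV/CSV with gene
rows and a header of cell ids; sparse matrices as MatrixMarket
coordinate files with one-column ``genes.txt`` / ``cells.txt`` sidecars.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

RAW_COUNTS = "raw_counts"
NORMALIZED_LOG = "normalized_log"
_STATES = (RAW_COUNTS, NORMALIZED_LOG)


def _check_unique(names: Sequence[str], axis: str) -> None:
    seen: dict[str, int] = {}
    for n in names:
        seen[n] = seen.get(n, 0) + 1
    dups = sorted(n for n, c in seen.items() if c > 1)
    if dups:
        raise ValueError(f"duplicate {axis} names: {dups}")


@dataclass
class ExpressionMatrix:
    """Named genes × cells expression matrix.

    Parameters
    ----------
    values
        Non-negative numeric matrix, one row per gene, one column per cell.
    gene_names, cell_ids
        Unique, ordered axis names.
    state
        ``"raw_counts"`` or ``"normalized_log"``.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    state: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.state not in _STATES:
            raise ValueError(f"state must be one of {_STATES}, got {self.state!r}")
        if len(self.gene_names) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {self.values.shape[0]} rows"
            )
        if len(self.cell_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {self.values.shape[1]} columns"
            )
        _check_unique(self.gene_names, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in expression matrix")
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative entry at gene {self.gene_names[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing[:10]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            self.values[rows], list(genes), list(self.cell_ids), self.state
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_names, columns=self.cell_ids)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def read_expression(
    path: str | os.PathLike,
    format: str | None = None,
    orientation: str = "genes-by-cells",
    genes_file: str | os.PathLike | None = None,
    cells_file: str | os.PathLike | None = None,
    state: str = RAW_COUNTS,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV or MatrixMarket.

    MTX input expects sidecar files ``genes.txt`` and ``cells.txt`` next
    to the matrix unless explicit paths are given.  ``orientation``
    declares the layout of the file; the returned matrix is always
    genes × cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format or _infer_format(path)
    if orientation not in ("genes-by-cells", "cells-by-genes"):
        raise ValueError(f"unknown orientation {orientation!r}")

    if fmt == "mtx":
        genes_file = Path(genes_file) if genes_file else path.parent / "genes.txt"
        cells_file = Path(cells_file) if cells_file else path.parent / "cells.txt"
        for side in (genes_file, cells_file):
            if not side.exists():
                raise FileNotFoundError(f"MTX sidecar missing: {side}")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy message passthrough
            raise ValueError(f"malformed MatrixMarket file {path}: {exc}") from exc
        values = np.asarray(
            mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        rows = [ln.strip() for ln in genes_file.read_text().splitlines() if ln.strip()]
        cols = [ln.strip() for ln in cells_file.read_text().splitlines() if ln.strip()]
    elif fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise ValueError(f"malformed {fmt.upper()} file {path}: {exc}") from exc
        if not all(
            np.issubdtype(dt, np.number) for dt in df.dtypes
        ):
            bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ValueError(f"non-numeric columns in {path}: {bad[:5]}")
        values = df.to_numpy(dtype=float)
        rows = [str(i) for i in df.index]
        cols = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if orientation == "cells-by-genes":
        values = values.T
        rows, cols = cols, rows
    return ExpressionMatrix(values, rows, cols, state=state)


def write_expression(
    em: ExpressionMatrix,
    path: str | os.PathLike,
    format: str | None = None,
) -> None:
    """Write a matrix as dense TSV/CSV or MTX with sidecars (genes × cells)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        scipy.io.mmwrite(
            path, scipy.sparse.coo_matrix(em.values), precision=12
        )
        (path.parent / "genes.txt").write_text("\n".join(em.gene_names) + "\n")
        (path.parent / "cells.txt").write_text("\n".join(em.cell_ids) + "\n")
    elif fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        em.to_frame().to_csv(path, sep=sep, float_format="%.12g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_labels(path: str | os.PathLike) -> dict[str, str]:
    """Read per-cell labels from a two-column TSV (cell_id, label)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"expected two columns (cell_id, label) in {path}")
    cells = df.iloc[:, 0].tolist()
    _check_unique(cells, "cell")
    return dict(zip(cells, df.iloc[:, 1].tolist()))


def write_labels(labels: dict[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"cell_id": list(labels.keys()), "label": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)
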