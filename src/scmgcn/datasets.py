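"""Expression-matrix container and readers/writers.

The central object is :class:`ExpressionDataset`, a cells × genes count (or
normalized) matrix together with cell identifiers, gene identifiers and,
for reference datasets, per-cell type labels.  Matrices are held as
``scipy.sparse.csr_matrix`` regardless of the on-disk format.

Supported formats: Matrix Market triplets with plain-text row/column name
sidecars, delimited text (CSV/TSV, cells as rows by default), and AnnData
HDF5 (``.h5ad``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
]


class FormatError(ValueError):
    """Raised when a file's contents are inconsistent with its format."""


@dataclass
class ExpressionDataset:
    """A cells × genes expression matrix with identifiers and optional labels.

    Parameters
    ----------
    matrix
        Non-negative cells × genes matrix (CSR).  Raw-count matrices must be
        integer-valued; set ``normalized=True`` for continuous values.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    labels
        Per-cell type labels.  Mandatory when ``role == "reference"``.
    role
        ``"reference"`` (annotated, supplies labels for training) or
        ``"query"`` (labels, if present, are used only for evaluation).
    normalized
        Whether the matrix holds normalized (and possibly log-transformed)
        values rather than raw counts.
    """

    matrix: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    labels: np.ndarray | None = None
    role: str = "reference"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n, m = self.matrix.shape
        if n != len(self.cell_ids) or m != len(self.gene_ids):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.cell_ids)} cell ids / {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids are not unique")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("expression matrix contains negative entries")
        if not self.normalized and self.matrix.nnz:
            data = self.matrix.data
            if not np.allclose(data, np.round(data)):
                raise ValueError("raw-count matrix contains non-integer entries")
        if self.role not in ("reference", "query"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "reference" and self.labels is None:
            raise ValueError("reference datasets require labels for every cell")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match number of cells")

    # -- conveniences -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def dense(self, dtype=np.float64) -> np.ndarray:
        return np.asarray(self.matrix.todense(), dtype=dtype)

    def subset_cells(self, index: np.ndarray) -> "ExpressionDataset":
        labels = self.labels[index] if self.labels is not None else None
        return replace(
            self,
            matrix=self.matrix[index],
            cell_ids=self.cell_ids[index],
            labels=labels,
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionDataset":
        return replace(
            self, matrix=self.matrix[:, index], gene_ids=self.gene_ids[index]
        )

    def reorder_genes(self, gene_ids) -> "ExpressionDataset":
        """Restrict and reorder columns to ``gene_ids`` (all must be present)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            index = np.array([pos[g] for g in gene_ids], dtype=int)
        except KeyError as err:
            raise ValueError(f"gene {err.args[0]!r} not in dataset") from None
        return self.subset_genes(index)


def _collapse_duplicate_genes(
    matrix: sp.csr_matrix, gene_ids: np.ndarray
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sum columns that share a gene id, keeping first-occurrence order."""
    unique, inverse = np.unique(gene_ids, return_inverse=True)
    if len(unique) == len(gene_ids):
        return matrix, gene_ids
    n_dup = len(gene_ids) - len(unique)
    logger.warning("collapsing %d duplicated gene ids by summation", n_dup)
    warnings.warn(f"collapsed {n_dup} duplicated gene ids by summation")
    first_seen: dict[str, int] = {}
    order = []
    for g in gene_ids:
        if g not in first_seen:
            first_seen[g] = len(order)
            order.append(g)
    # indicator: old column -> new column
    col_map = np.array([first_seen[g] for g in gene_ids])
    indicator = sp.csr_matrix(
        (np.ones(len(gene_ids)), (np.arange(len(gene_ids)), col_map)),
        shape=(len(gene_ids), len(order)),
    )
    return sp.csr_matrix(matrix @ indicator), np.asarray(order, dtype=object)


def _read_names(path: Path) -> np.ndarray:
    names = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return np.asarray(names, dtype=object)


def read_expression(
    path,
    format: str | None = None,
    *,
    cells_as_rows: bool = True,
    role: str = "query",
    labels: np.ndarray | None = None,
    normalized: bool = False,
) -> ExpressionDataset:
    """Read an expression matrix from MTX (+ sidecars), CSV/TSV or h5ad.

    For MTX, ``<stem>_rows.tsv`` and ``<stem>_cols.tsv`` sidecars must hold
    the row and column names.  ``cells_as_rows=False`` transposes delimited
    and MTX input.  Duplicate gene ids are collapsed by summation.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"expression file not found: {path}")
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".h5ad": "h5ad"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path}")

    if format == "mtx":
        matrix = sp.csr_matrix(mmread(path))
        rows_path = path.with_name(path.stem + "_rows.tsv")
        cols_path = path.with_name(path.stem + "_cols.tsv")
        for p in (rows_path, cols_path):
            if not p.exists():
                raise IOError(f"missing MTX sidecar: {p}")
        row_names, col_names = _read_names(rows_path), _read_names(cols_path)
        if matrix.shape != (len(row_names), len(col_names)):
            raise FormatError(
                f"MTX shape {matrix.shape} does not match sidecar name counts "
                f"({len(row_names)}, {len(col_names)})"
            )
        if not cells_as_rows:
            matrix, row_names, col_names = sp.csr_matrix(matrix.T), col_names, row_names
        cell_ids, gene_ids = row_names, col_names
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        # pandas mangles duplicate header names (g1 -> g1.1); restore originals
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(header) == df.shape[1]:
            df.columns = header
        if not cells_as_rows:
            df = df.T
        matrix = sp.csr_matrix(df.to_numpy())
        cell_ids = np.asarray(df.index.astype(str), dtype=object)
        gene_ids = np.asarray(df.columns.astype(str), dtype=object)
    elif format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        matrix = sp.csr_matrix(adata.X)
        cell_ids = np.asarray(adata.obs_names.astype(str), dtype=object)
        gene_ids = np.asarray(adata.var_names.astype(str), dtype=object)
        if labels is None and "cell_type" in adata.obs:
            labels = np.asarray(adata.obs["cell_type"].astype(str), dtype=object)
    else:
        raise ValueError(f"unknown format {format!r}")

    matrix, gene_ids = _collapse_duplicate_genes(matrix, gene_ids)
    return ExpressionDataset(
        matrix=matrix, cell_ids=cell_ids, gene_ids=gene_ids, labels=labels,
        role=role, normalized=normalized,
    )


def write_expression(ds: ExpressionDataset, path, format: str = "mtx") -> None:
    """Write a dataset as MTX (+ name sidecars), CSV/TSV or h5ad."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        mmwrite(str(path), ds.matrix)
        path.with_name(path.stem + "_rows.tsv").write_text(
            "\n".join(map(str, ds.cell_ids)) + "\n"
        )
        path.with_name(path.stem + "_cols.tsv").write_text(
            "\n".join(map(str, ds.gene_ids)) + "\n"
        )
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        pd.DataFrame(
            ds.dense(), index=list(ds.cell_ids), columns=list(ds.gene_ids)
        ).to_csv(path, sep=sep)
    elif format == "h5ad":
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(list(ds.cell_ids), name="cell_id"))
        if ds.labels is not None:
            obs["cell_type"] = list(ds.labels)
        adata = ad.AnnData(
            X=ds.matrix.copy(),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(list(ds.gene_ids), name="gene_id")),
        )
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path) -> pd.Series:
    """Read a two-column TSV (cell_id, type) into a Series indexed by cell id."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"label file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "type"], dtype=str)
    return df.set_index("cell_id")["type"]


def write_labels(cell_ids, labels, path) -> None:
    pd.DataFrame({"cell_id": list(cell_ids), "type": list(labels)}).to_csv(
        path, sep="\t", header=False, index=False
    )
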