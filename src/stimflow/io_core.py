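"""Shared data containers and on-disk formats.

The central container is :class:`ExpressionDataset`, a cells x genes
matrix together with per-cell metadata (timepoint label, replicate,
optional cluster and pseudotime columns) and a state flag tracking
which normalization has been applied.  :class:`TimepointDesign` encodes
the ordered experimental timepoints and their integer codes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

STATES = ("raw", "l2", "standardized")

#: metadata column names used throughout the package
TIME_COL = "timepoint"
REPLICATE_COL = "replicate"
CLUSTER_COL = "cluster"
PSEUDOTIME_COL = "pseudotime"


class FormatError(ValueError):
    """Raised when an on-disk artifact is malformed or inconsistent."""


@dataclass
class ExpressionDataset:
    """Cells x genes expression matrix with aligned per-cell metadata.

    Parameters
    ----------
    matrix
        Dense ndarray or scipy sparse matrix, cells as rows.
    cell_meta
        DataFrame indexed by cell barcode, one row per matrix row.
    gene_names
        Unique gene identifiers, one per matrix column.
    state
        Normalization state: ``raw`` counts, ``l2`` (unit-norm cells)
        or ``standardized`` (zero-mean, unit-variance genes).
    embedding
        Optional cells x dims numeric embedding (e.g. an integrated
        low-dimensional space supplied by an external tool).
    """

    matrix: np.ndarray | sp.spmatrix
    cell_meta: pd.DataFrame
    gene_names: list[str] = field(default_factory=list)
    state: str = "raw"
    embedding: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        n, g = self.matrix.shape
        if len(self.cell_meta) != n:
            raise ValueError(
                f"cell_meta has {len(self.cell_meta)} rows but matrix has {n} cells"
            )
        self.gene_names = [str(x) for x in self.gene_names]
        if len(self.gene_names) != g:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {g} matrix columns"
            )
        dupes = pd.Index(self.gene_names)[pd.Index(self.gene_names).duplicated()]
        if len(dupes):
            raise FormatError(f"duplicate gene names: {sorted(set(dupes))[:5]}")
        if self.embedding is not None and self.embedding.shape[0] != n:
            raise ValueError("embedding row count does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def dense(self) -> np.ndarray:
        """Matrix as a dense float ndarray (copy if sparse)."""
        if sp.issparse(self.matrix):
            return np.asarray(self.matrix.todense(), dtype=float)
        return np.asarray(self.matrix, dtype=float)

    def with_matrix(self, matrix, state: str | None = None) -> "ExpressionDataset":
        return replace(self, matrix=matrix, state=state or self.state)

    def subset_cells(self, mask) -> "ExpressionDataset":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        emb = self.embedding[idx] if self.embedding is not None else None
        mat = self.matrix[idx]
        return ExpressionDataset(
            matrix=mat,
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_names=list(self.gene_names),
            state=self.state,
            embedding=emb,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        idx = np.array([lookup[g] for g in genes], dtype=int)
        mat = self.matrix[:, idx]
        return ExpressionDataset(
            matrix=mat,
            cell_meta=self.cell_meta.copy(),
            gene_names=list(genes),
            state=self.state,
            embedding=None if self.embedding is None else self.embedding.copy(),
        )


@dataclass(frozen=True)
class TimepointDesign:
    """Ordered experimental timepoint labels mapped to codes 0..m.

    The default coding is equally spaced ordinals (0, 1, 2, ...);
    ``numeric_codes`` overrides them with user-supplied values such as
    log-scaled hours.
    """

    labels: tuple[str, ...]
    numeric_codes: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValueError("design needs at least one timepoint label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate timepoint labels in design")
        if self.numeric_codes is not None and len(self.numeric_codes) != len(
            self.labels
        ):
            raise ValueError("numeric_codes length must match labels")

    @property
    def codes(self) -> dict[str, float]:
        if self.numeric_codes is not None:
            return dict(zip(self.labels, self.numeric_codes))
        return {lab: float(i) for i, lab in enumerate(self.labels)}

    @property
    def n_timepoints(self) -> int:
        return len(self.labels)


def assign_time_codes(
    dataset: ExpressionDataset, design: TimepointDesign, column: str = TIME_COL
) -> np.ndarray:
    """Map each cell's timepoint label to its design code.

    Raises ``ValueError`` listing offending cells if any label is not
    in the design.
    """
    labels = dataset.cell_meta[column].astype(str)
    codes = design.codes
    unknown = labels[~labels.isin(codes)]
    if len(unknown):
        cells = list(unknown.index[:10])
        raise ValueError(
            f"{len(unknown)} cells carry timepoint labels not in the design "
            f"{design.labels}; first offenders: {cells}"
        )
    return labels.map(codes).to_numpy(dtype=float)


def _read_mtx_dir(path: str) -> tuple[sp.csr_matrix, list[str], list[str]]:
    mtx_path = os.path.join(path, "matrix.mtx")
    genes_path = os.path.join(path, "genes.tsv")
    barcodes_path = os.path.join(path, "barcodes.tsv")
    for p in (mtx_path, genes_path, barcodes_path):
        if not os.path.exists(p):
            raise FormatError(f"missing file: {p}")
    mat = sp.csr_matrix(scipy.io.mmread(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    # 10x convention stores genes x cells; flip to cells x genes if needed
    if mat.shape == (len(genes), len(barcodes)) and mat.shape[0] != mat.shape[1]:
        mat = sp.csr_matrix(mat.T)
    if mat.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"matrix shape {mat.shape} inconsistent with {len(barcodes)} barcodes "
            f"and {len(genes)} genes"
        )
    return mat, genes, barcodes


def read_counts(path: str, format: str = "mtx_triplet") -> ExpressionDataset:
    """Read a raw-count dataset from disk.

    ``mtx_triplet`` expects a directory with ``matrix.mtx``,
    ``genes.tsv``, ``barcodes.tsv`` and optionally ``cell_meta.csv``
    (indexed by barcode).  ``csv`` expects a dense table with a header
    row of gene names and barcodes in the first column.  Cells are rows
    in the returned dataset regardless of on-disk orientation.
    """
    if format == "mtx_triplet":
        mat, genes, barcodes = _read_mtx_dir(path)
        meta_path = os.path.join(path, "cell_meta.csv")
        if os.path.exists(meta_path):
            meta = pd.read_csv(meta_path, index_col=0)
            meta.index = meta.index.astype(str)
            meta = meta.reindex(barcodes)
        else:
            meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
        return ExpressionDataset(matrix=mat, cell_meta=meta, gene_names=genes)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        meta = pd.DataFrame(index=df.index.astype(str))
        return ExpressionDataset(
            matrix=df.to_numpy(dtype=float),
            cell_meta=meta,
            gene_names=[str(c) for c in df.columns],
        )
    raise ValueError(f"unknown format {format!r}")


def write_counts(dataset: ExpressionDataset, path: str) -> None:
    """Write a dataset as an MTX triplet directory plus metadata CSV."""
    os.makedirs(path, exist_ok=True)
    mat = dataset.matrix
    if not sp.issparse(mat):
        mat = sp.coo_matrix(np.asarray(mat))
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sp.coo_matrix(mat))
    pd.Series(dataset.gene_names).to_csv(
        os.path.join(path, "genes.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(dataset.cell_meta.index.astype(str)).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    if len(dataset.cell_meta.columns):
        dataset.cell_meta.to_csv(os.path.join(path, "cell_meta.csv"))
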