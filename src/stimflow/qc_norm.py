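"""Cell filtering, normalization and highly-variable-gene ranking.

QC drops cells with a high mitochondrial-count fraction or too few
detected genes.  Normalization is per-cell L2 scaling followed, where
needed downstream, by per-gene standardization.  Highly variable genes
are ranked by the variance of analytic Pearson residuals computed on
raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from stimflow.io_core import ExpressionDataset


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC thresholds.

    Cells are kept when their mitochondrial-count fraction is at most
    ``max_mito_fraction`` and they express at least ``min_unique_genes``
    distinct genes.  Mitochondrial genes are recognized by a
    case-insensitive name prefix.
    """

    max_mito_fraction: float = 0.05
    min_unique_genes: int = 700
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.min_unique_genes < 0:
            raise ValueError("min_unique_genes must be >= 0")


def filter_cells(
    dataset: ExpressionDataset, thresholds: QCThresholds = QCThresholds()
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Apply QC thresholds; return the surviving cells and a report.

    The report has one row per input cell with columns ``keep``
    (bool), ``reason`` (empty for kept cells, otherwise
    ``mito``/``genes``/``mito;genes``), ``mito_fraction`` and
    ``n_unique_genes``.
    """
    if dataset.state != "raw":
        raise ValueError("filter_cells expects raw counts")
    X = dataset.matrix
    mito_mask = np.array(
        [g.lower().startswith(thresholds.mito_prefix.lower()) for g in dataset.gene_names]
    )
    if sp.issparse(X):
        totals = np.asarray(X.sum(axis=1)).ravel()
        mito_counts = np.asarray(X[:, np.flatnonzero(mito_mask)].sum(axis=1)).ravel()
        n_unique = np.asarray((X != 0).sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        totals = X.sum(axis=1)
        mito_counts = X[:, mito_mask].sum(axis=1)
        n_unique = (X != 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 0.0)

    apply_mito = True
    if not mito_mask.any() and thresholds.max_mito_fraction < 1.0:
        warnings.warn(
            f"no gene names match mito prefix {thresholds.mito_prefix!r}; "
            "mitochondrial filter skipped",
            stacklevel=2,
        )
        apply_mito = False

    fail_mito = apply_mito & (mito_frac > thresholds.max_mito_fraction)
    fail_genes = n_unique < thresholds.min_unique_genes
    keep = ~(fail_mito | fail_genes)

    reasons = np.where(
        fail_mito & fail_genes,
        "mito;genes",
        np.where(fail_mito, "mito", np.where(fail_genes, "genes", "")),
    )
    report = pd.DataFrame(
        {
            "keep": keep,
            "reason": reasons,
            "mito_fraction": mito_frac,
            "n_unique_genes": n_unique,
        },
        index=dataset.cell_meta.index,
    )
    return dataset.subset_cells(keep), report


def l2_normalize_cells(dataset: ExpressionDataset) -> ExpressionDataset:
    """Scale each cell row to unit Euclidean norm (state ``l2``).

    Idempotent.  Raises on all-zero cells, naming the first offenders.
    """
    X = dataset.dense()
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        cells = list(dataset.cell_meta.index[zero][:10])
        raise ValueError(f"cannot L2-normalize all-zero cells: {cells}")
    return dataset.with_matrix(X / norms[:, None], state="l2")


def pearson_residual_hvgs(
    dataset: ExpressionDataset,
    n_top: int,
    theta: float = 100.0,
    clip: float | None = None,
) -> pd.DataFrame:
    """Rank genes by analytic Pearson residual variance on raw counts.

    Residuals are r = (x - mu) / sqrt(mu + mu^2/theta) with mu the
    product of row and column sums over the grand total, clipped to
    +/- sqrt(N) (or ``clip``).  Returns the top ``n_top`` genes as a
    DataFrame with columns ``gene`` and ``residual_variance``, ordered
    by decreasing variance (ties by input gene order).
    """
    if dataset.state != "raw":
        raise ValueError("pearson_residual_hvgs expects raw counts")
    if n_top > dataset.n_genes:
        raise ValueError(
            f"n_top={n_top} exceeds gene count {dataset.n_genes}"
        )
    X = dataset.dense()
    n = X.shape[0]
    row = X.sum(axis=1, keepdims=True)
    col = X.sum(axis=0, keepdims=True)
    total = X.sum()
    if total == 0:
        raise ValueError("all-zero count matrix")
    mu = row @ col / total
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = (X - mu) / np.sqrt(mu + mu**2 / theta)
    resid = np.nan_to_num(resid, nan=0.0, posinf=0.0, neginf=0.0)
    bound = np.sqrt(n) if clip is None else clip
    resid = np.clip(resid, -bound, bound)
    var = resid.var(axis=0)
    # stable sort keeps input order among exact ties
    order = np.argsort(-var, kind="stable")[:n_top]
    return pd.DataFrame(
        {
            "gene": [dataset.gene_names[i] for i in order],
            "residual_variance": var[order],
        }
    ).reset_index(drop=True)


def standardize_genes(
    dataset: ExpressionDataset, force: bool = False
) -> tuple[ExpressionDataset, list[str]]:
    """Per-gene zero-mean unit-variance scaling (state ``standardized``).

    Variance uses the population (1/N) convention.  Zero-variance genes
    are dropped and returned as the second element.  Expects an
    L2-normalized dataset unless ``force`` is set (e.g. for simulated
    continuous expression that is not count-derived).
    """
    if dataset.state != "l2" and not force:
        raise ValueError(
            "standardize_genes expects an l2-state dataset; pass force=True to override"
        )
    X = dataset.dense()
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population convention
    keep = std > 0
    if not keep.any():
        raise ValueError("all genes have zero variance")
    dropped = [g for g, k in zip(dataset.gene_names, keep) if not k]
    Z = (X[:, keep] - mean[keep]) / std[keep]
    out = ExpressionDataset(
        matrix=Z,
        cell_meta=dataset.cell_meta.copy(),
        gene_names=[g for g, k in zip(dataset.gene_names, keep) if k],
        state="standardized",
        embedding=None if dataset.embedding is None else dataset.embedding.copy(),
    )
    return out, dropped
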