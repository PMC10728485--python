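"""Semi-supervised response pseudotime and pseudotemporal patterns.

The pseudotime model looks for the gene-weight vector W such that the
linear projection X @ W of standardized expression best reconstructs
each cell's experimental time code T in the least-squares sense
(without an intercept by default).  The projection PT = X @ W is the
per-cell response pseudotime; cells are then ordered along it, gene
expression is smoothed in consecutive bins of ordered cells, and the
smoothed, min-max scaled profiles are grouped into pseudotemporal
patterns by hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from stimflow.change_similarity import _relabel_by_size


@dataclass
class PseudotimeModel:
    """Fitted weights, per-cell pseudotime and residuals."""

    W: np.ndarray  # (G,)
    PT: np.ndarray  # (N,)
    residuals: np.ndarray  # (N,) PT - T (+ intercept if fitted)
    T: np.ndarray  # (N,)
    gene_names: list[str] | None = None
    intercept: float | None = None
    rank: int = 0


@dataclass
class PatternAssignment:
    """Per-gene pseudotemporal pattern ids with the smoothed profiles."""

    pattern: pd.Series  # gene -> 1-based pattern id, ordered by size
    smoothed: pd.DataFrame  # genes x bins, min-max scaled
    bin_size: int
    threshold: float

    @property
    def n_patterns(self) -> int:
        return int(self.pattern.max())


def fit_response_pseudotime(
    X: np.ndarray,
    T: np.ndarray,
    gene_names: list[str] | None = None,
    intercept: bool = False,
) -> PseudotimeModel:
    """Least-squares fit of per-gene weights reconstructing time codes.

    Solves min_W ||X W - T||^2 with a numerically stable routine
    (SVD-based lstsq, never explicit normal-equation inversion) and
    returns PT = X @ W plus residuals PT - T.  Requires more cells than
    genes; a rank-deficient X yields the minimum-norm solution with a
    warning.

    Parameters
    ----------
    X
        Standardized cells x genes matrix (zero mean, unit variance per
        gene).
    T
        Per-cell numeric time codes (e.g. 0, 1, 2, 3 for four ordered
        timepoints).
    intercept
        Fit an additive constant as well.  PT then includes the
        intercept so that PT - T remains the model residual.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-d (cells x genes)")
    n, g = X.shape
    if T.shape[0] != n:
        raise ValueError(f"T has {T.shape[0]} entries for {n} cells")
    n_params = g + (1 if intercept else 0)
    if n_params >= n:
        raise ValueError(
            f"{g} genes (+{int(intercept)} intercept) >= {n} cells; reduce the "
            "gene set so the regression is identifiable"
        )
    if gene_names is not None and len(gene_names) != g:
        raise ValueError("gene_names length does not match X columns")

    A = np.column_stack([X, np.ones(n)]) if intercept else X
    coef, _, rank, _ = np.linalg.lstsq(A, T, rcond=None)
    if rank < n_params:
        warnings.warn(
            f"design matrix is rank deficient (rank {rank} < {n_params}); "
            "returning the minimum-norm solution",
            stacklevel=2,
        )
    if intercept:
        W, b = coef[:-1], float(coef[-1])
        PT = X @ W + b
    else:
        W, b = coef, None
        PT = X @ W
    return PseudotimeModel(
        W=W,
        PT=PT,
        residuals=PT - T,
        T=T,
        gene_names=list(gene_names) if gene_names is not None else None,
        intercept=b,
        rank=int(rank),
    )


def order_cells(model: PseudotimeModel) -> np.ndarray:
    """Cell indices in ascending pseudotime; exact ties keep input order."""
    return np.argsort(model.PT, kind="stable")


def smooth_pattern_matrix(
    X: np.ndarray,
    order: np.ndarray,
    gene_names: list[str] | None = None,
    bin_size: int = 100,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean expression per bin of ``bin_size`` consecutive ordered cells.

    Cells are sorted by ``order`` and cut into disjoint bins.  A final
    partial bin is kept as its own bin when it holds at least half of
    ``bin_size`` cells and merged into the previous bin otherwise.  Bin
    means are then min-max scaled per gene to [0, 1]; constant genes
    are set to zero and flagged in the returned boolean array.

    Returns (genes x bins DataFrame, degenerate flags per gene).
    """
    X = np.asarray(X, dtype=float)
    order = np.asarray(order, dtype=int)
    n = X.shape[0]
    if order.shape[0] != n:
        raise ValueError("order length does not match cell count")
    if bin_size < 1:
        raise ValueError("bin_size must be positive")
    if n < bin_size:
        warnings.warn(
            f"only {n} cells for bin_size={bin_size}; using a single bin",
            stacklevel=2,
        )
        edges = [0, n]
    else:
        n_full, rem = divmod(n, bin_size)
        edges = [i * bin_size for i in range(n_full + 1)]
        if rem >= bin_size / 2:
            edges.append(n)
        else:
            edges[-1] = n  # merge remainder into the last full bin
    Xo = X[order]
    bins = np.stack(
        [Xo[lo:hi].mean(axis=0) for lo, hi in zip(edges[:-1], edges[1:])], axis=1
    )  # (G, B)
    lo = bins.min(axis=1, keepdims=True)
    span = bins.max(axis=1, keepdims=True) - lo
    degenerate = span[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (bins - lo) / span
    scaled[degenerate] = 0.0
    index = gene_names if gene_names is not None else list(range(X.shape[1]))
    return pd.DataFrame(scaled, index=index), degenerate


def cluster_patterns(
    smoothed: pd.DataFrame,
    threshold: float = 5.2,
    linkage: str = "ward",
    bin_size: int = 100,
) -> PatternAssignment:
    """Hierarchically cluster smoothed gene profiles into patterns.

    Flat patterns are cut at the given cophenetic-distance threshold;
    pattern ids are 1-based, ordered by descending pattern size.
    """
    if len(smoothed) < 2:
        raise ValueError("need at least 2 genes to cluster patterns")
    Z = scipy_linkage(smoothed.to_numpy(), method=linkage)
    raw = fcluster(Z, t=threshold, criterion="distance")
    pattern = pd.Series(_relabel_by_size(raw), index=smoothed.index, name="pattern")
    return PatternAssignment(
        pattern=pattern, smoothed=smoothed, bin_size=bin_size, threshold=threshold
    )
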