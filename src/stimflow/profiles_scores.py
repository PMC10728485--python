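"""Gene-set scoring and smoothed pseudotemporal profile curves.

The gene-set score is the classic control-pool construction: per cell,
mean expression over the set minus mean expression over reference
genes drawn from matching expression bins.  Profile curves summarize a
quantity (single-gene expression or a per-cell score) along the
pseudotime ordering using bootstrapped smoothing — rolling-mean bins
for genes, first-order LOESS for scores — with 95% confidence bands
from 1.96 x the standard error across bootstrap replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from stimflow.io_core import ExpressionDataset


@dataclass
class GeneSetScore:
    """Per-cell gene-set score with the reference pool used."""

    scores: np.ndarray
    set_name: str
    seed: int
    set_genes: list[str]
    reference_genes: list[str]


@dataclass
class ProfileCurve:
    """Smoothed mean curve with a 95% confidence band.

    ``grid`` holds positions along the pseudotime-rank fraction in
    [0, 1]; ``lower <= mean <= upper`` pointwise.
    """

    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    window: int | None
    reps: int

    def __post_init__(self) -> None:
        eps = 1e-12
        if ((self.lower > self.mean + eps) | (self.mean > self.upper + eps)).any():
            raise ValueError("confidence band does not bracket the mean")


def score_gene_set(
    dataset: ExpressionDataset,
    gene_set: list[str],
    set_name: str = "score",
    n_bins: int = 25,
    ctrl_per_gene: int = 1,
    seed: int = 0,
) -> GeneSetScore:
    """Mean set expression minus mean matched-reference expression.

    Genes are ranked by mean expression across cells and cut into
    ``n_bins`` equal-size bins; for each set gene, ``ctrl_per_gene``
    reference genes are drawn uniformly from its bin, excluding set
    genes.  Set genes missing from the dataset are dropped with a
    warning; an empty intersection is an error.  Deterministic for a
    fixed seed.
    """
    if dataset.state != "standardized":
        raise ValueError("score_gene_set expects a standardized dataset")
    present = [g for g in gene_set if g in set(dataset.gene_names)]
    missing = sorted(set(gene_set) - set(present))
    if not present:
        raise ValueError("gene set has no overlap with dataset genes")
    if missing:
        import warnings

        warnings.warn(f"{len(missing)} set genes absent from dataset: {missing[:5]}",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    X = dataset.dense()
    gene_index = {g: i for i, g in enumerate(dataset.gene_names)}
    mean_expr = pd.Series(X.mean(axis=0), index=dataset.gene_names)
    # equal-size bins on the expression rank, like score_genes-style pools
    ranks = mean_expr.rank(method="first")
    bin_of = np.ceil(ranks / len(ranks) * n_bins).astype(int)

    set_idx = [gene_index[g] for g in present]
    set_lookup = set(present)
    reference: list[str] = []
    for g in present:
        pool = bin_of.index[(bin_of == bin_of[g]) & (~bin_of.index.isin(set_lookup))]
        if len(pool) == 0:
            continue  # bin exhausted by set genes; skip its control draw
        k = min(ctrl_per_gene, len(pool))
        reference.extend(rng.choice(pool, size=k, replace=False).tolist())
    if not reference:
        raise ValueError("no reference genes available outside the gene set")
    ref_idx = [gene_index[g] for g in reference]
    scores = X[:, set_idx].mean(axis=1) - X[:, ref_idx].mean(axis=1)
    return GeneSetScore(
        scores=scores,
        set_name=set_name,
        seed=seed,
        set_genes=present,
        reference_genes=reference,
    )


def _rolling_profile(values: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered full-window rolling mean; returns (rank fractions, means)."""
    m = len(values)
    kernel = np.full(window, 1.0 / window)
    smoothed = np.convolve(values, kernel, mode="valid")
    # centers of the valid windows, as rank fractions of the subsample
    centers = np.arange(len(smoothed)) + (window - 1) / 2.0
    frac = centers / (m - 1) if m > 1 else np.array([0.5])
    return frac, smoothed


def bootstrap_gene_profile(
    values: np.ndarray,
    order: np.ndarray,
    window: int = 600,
    reps: int = 20,
    frac: float = 0.5,
    seed: int = 0,
    grid_size: int = 200,
) -> ProfileCurve:
    """Bootstrapped rolling-mean profile of one gene along pseudotime.

    Per replicate, ``frac`` of the cells are sampled without
    replacement, kept in pseudotime order, and smoothed with a centered
    rolling mean of ``window`` cells; the curve is interpolated onto a
    common rank-fraction grid.  The profile is the across-replicate
    mean with a mean +/- 1.96 x SE band.
    """
    values = np.asarray(values, dtype=float).ravel()
    order = np.asarray(order, dtype=int)
    n = len(values)
    if len(order) != n:
        raise ValueError("order length does not match values")
    m = int(np.floor(frac * n))
    if window > m:
        raise ValueError(
            f"window={window} exceeds the subsample size {m}; choose a smaller window"
        )
    rng = np.random.default_rng(seed)
    ordered = values[order]
    grid = np.linspace(0.0, 1.0, grid_size)
    curves = np.empty((reps, grid_size))
    for r in range(reps):
        keep = np.sort(rng.choice(n, size=m, replace=False))
        frac_pos, smoothed = _rolling_profile(ordered[keep], window)
        curves[r] = np.interp(grid, frac_pos, smoothed)
    mean = curves.mean(axis=0)
    se = curves.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.zeros(grid_size)
    return ProfileCurve(
        grid=grid,
        mean=mean,
        lower=mean - 1.96 * se,
        upper=mean + 1.96 * se,
        window=window,
        reps=reps,
    )


def loess_score_profile(
    score: GeneSetScore | np.ndarray,
    order: np.ndarray,
    reps: int = 30,
    frac: float = 0.5,
    degree: int = 1,
    span: float = 0.3,
    seed: int = 0,
    grid_size: int = 200,
) -> ProfileCurve:
    """Bootstrapped first-order LOESS profile of a per-cell score.

    Per replicate, the score is regressed against pseudotime-rank
    fraction on a ``frac`` subsample with locally weighted linear
    regression (tricube weights, span ``span``) and evaluated on a
    common grid; mean and 1.96 x SE band are taken across replicates.
    """
    values = score.scores if isinstance(score, GeneSetScore) else np.asarray(score)
    values = np.asarray(values, dtype=float).ravel()
    order = np.asarray(order, dtype=int)
    n = len(values)
    if len(order) != n:
        raise ValueError("order length does not match score length")
    if degree != 1:
        raise NotImplementedError("only first-order (degree=1) LOESS is supported")
    m = int(np.floor(frac * n))
    if m < 10:
        raise ValueError(f"subsample of {m} cells is too small (need >= 10)")
    if span * m < 2:
        raise ValueError(
            f"span={span} gives local neighborhoods of fewer than 2 points"
        )
    rng = np.random.default_rng(seed)
    ordered = values[order]
    grid = np.linspace(0.0, 1.0, grid_size)
    curves = np.empty((reps, grid_size))
    for r in range(reps):
        keep = np.sort(rng.choice(n, size=m, replace=False))
        x = keep / (n - 1)  # rank fraction within the full ordering
        y = ordered[keep]
        curves[r] = lowess(y, x, frac=span, it=0, xvals=grid)
    mean = curves.mean(axis=0)
    se = curves.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.zeros(grid_size)
    return ProfileCurve(
        grid=grid,
        mean=mean,
        lower=mean - 1.96 * se,
        upper=mean + 1.96 * se,
        window=None,
        reps=reps,
    )
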