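"""Change scores and cluster-vs-global profile similarity.

For every gene, the mean L2-normalized expression per (cluster,
timepoint) forms a short temporal profile.  The change score of a gene
in a cluster is the summed absolute consecutive difference of that
profile; genes are grouped by their per-cluster change-score vectors
via hierarchical clustering.  The similarity score compares each
cluster profile, min-max scaled, with the global ("all cells") profile
of the same gene: 1 means the cluster follows the global pattern
exactly, 0 means maximal disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from stimflow.io_core import CLUSTER_COL, TIME_COL, ExpressionDataset, TimepointDesign

ALL_CLUSTER = "all"


@dataclass
class ClusterTimeMeans:
    """Mean expression tensor mu[gene, cluster, timepoint].

    ``clusters`` includes the pseudo-cluster ``"all"`` holding the
    global (every-cell) profile.
    """

    values: np.ndarray  # (G, J, T)
    gene_names: list[str]
    clusters: list
    timepoints: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-d tensor (genes, clusters, timepoints)")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite mean expression values")
        if self.values.shape[2] < 2:
            raise ValueError("need at least 2 timepoints")
        if ALL_CLUSTER not in self.clusters:
            raise ValueError(f"missing {ALL_CLUSTER!r} pseudo-cluster")

    @property
    def n_intervals(self) -> int:
        return self.values.shape[2] - 1

    def cluster_index(self, cluster) -> int:
        return self.clusters.index(cluster)


@dataclass
class ChangeScoreMatrix:
    """Nonnegative genes x clusters change scores c[i, j]."""

    scores: pd.DataFrame  # genes x clusters


@dataclass
class PatternMatrix:
    """Min-max scaled profiles x[i, j, t] in [0, 1].

    Constant profiles cannot be scaled; they are set to all-zero and
    flagged in ``degenerate``.
    """

    values: np.ndarray  # (G, J, T)
    degenerate: np.ndarray  # (G, J) bool
    gene_names: list[str]
    clusters: list
    timepoints: list[str]


@dataclass
class SimilarityMatrix:
    """Genes x clusters similarity scores s[i, j] in [0, 1]."""

    scores: pd.DataFrame


def cluster_time_means(
    dataset: ExpressionDataset,
    design: TimepointDesign,
    cluster_col: str = CLUSTER_COL,
    time_col: str = TIME_COL,
) -> ClusterTimeMeans:
    """Arithmetic mean expression per (cluster, timepoint), zeros included.

    Requires an L2-normalized dataset and a non-empty cell group for
    every (cluster, timepoint) combination; an ``"all"`` pseudo-cluster
    averages over every cell at each timepoint.
    """
    if dataset.state != "l2":
        raise ValueError("cluster_time_means expects an l2-state dataset")
    X = dataset.dense()
    meta = dataset.cell_meta
    clusters = sorted(meta[cluster_col].unique(), key=str)
    timepoints = list(design.labels)
    tlab = meta[time_col].astype(str).to_numpy()
    clab = meta[cluster_col].to_numpy()

    empty = []
    values = np.zeros((dataset.n_genes, len(clusters) + 1, len(timepoints)))
    for ti, tp in enumerate(timepoints):
        at_t = tlab == tp
        if not at_t.any():
            empty.append((ALL_CLUSTER, tp))
            continue
        values[:, -1, ti] = X[at_t].mean(axis=0)
        for ci, cl in enumerate(clusters):
            rows = at_t & (clab == cl)
            if not rows.any():
                empty.append((cl, tp))
                continue
            values[:, ci, ti] = X[rows].mean(axis=0)
    if empty:
        raise ValueError(f"empty (cluster, timepoint) groups: {empty}")
    return ClusterTimeMeans(
        values=values,
        gene_names=list(dataset.gene_names),
        clusters=clusters + [ALL_CLUSTER],
        timepoints=timepoints,
    )


def change_score(means: ClusterTimeMeans, include_all: bool = False) -> ChangeScoreMatrix:
    """c[i, j] = sum over consecutive timepoints of |mu[t+1] - mu[t]|.

    With n timepoints there are exactly n - 1 summands.  The ``"all"``
    pseudo-cluster is excluded unless ``include_all``.
    """
    diffs = np.abs(np.diff(means.values, axis=2)).sum(axis=2)  # (G, J)
    df = pd.DataFrame(diffs, index=means.gene_names, columns=means.clusters)
    if not include_all:
        df = df.drop(columns=[ALL_CLUSTER])
    return ChangeScoreMatrix(scores=df)


def group_by_change(
    scores: ChangeScoreMatrix, threshold: float = 3.0, linkage: str = "ward"
) -> pd.Series:
    """Group genes by their change-score vectors.

    Agglomerative clustering of the gene rows, flat groups cut at the
    given cophenetic-distance threshold.  Group ids are 1-based and
    ordered by descending group size (ties by first occurrence).
    """
    mat = scores.scores.to_numpy()
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 genes to group")
    Z = scipy_linkage(mat, method=linkage)
    raw = fcluster(Z, t=threshold, criterion="distance")
    return pd.Series(
        _relabel_by_size(raw), index=scores.scores.index, name="group"
    )


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary flat-cluster ids to 1..K by descending size."""
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[x] for x in raw], dtype=int)


def pattern_minmax(means: ClusterTimeMeans) -> PatternMatrix:
    """Min-max scale each (gene, cluster) profile over timepoints.

    Constant profiles are flagged degenerate and set to zero at all
    timepoints.
    """
    mu = means.values
    lo = mu.min(axis=2, keepdims=True)
    hi = mu.max(axis=2, keepdims=True)
    span = hi - lo
    degenerate = span[:, :, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        x = (mu - lo) / span
    x[degenerate] = 0.0
    return PatternMatrix(
        values=x,
        degenerate=degenerate,
        gene_names=means.gene_names,
        clusters=list(means.clusters),
        timepoints=list(means.timepoints),
    )


def similarity_score(patterns: PatternMatrix) -> SimilarityMatrix:
    """s[i, j] = 1 - mean over timepoints of |x[i, all, t] - x[i, j, t]|."""
    if ALL_CLUSTER not in patterns.clusters:
        raise ValueError(f"patterns must include the {ALL_CLUSTER!r} pseudo-cluster")
    ai = patterns.clusters.index(ALL_CLUSTER)
    n = patterns.values.shape[2]
    diff = np.abs(patterns.values - patterns.values[:, ai : ai + 1, :])
    s = 1.0 - diff.sum(axis=2) / n
    df = pd.DataFrame(s, index=patterns.gene_names, columns=patterns.clusters)
    df = df.drop(columns=[ALL_CLUSTER])
    return SimilarityMatrix(scores=df)
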