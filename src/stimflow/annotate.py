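"""Control-subset clustering and KNN label transfer.

Cell identity is anchored in the unstimulated control subset: Leiden
communities are found there, and treated cells adopt the majority label
of their nearest control neighbors in a shared embedding.  This keeps
annotation robust to stimulation-induced marker shifts.

The integrated embedding itself is a pluggable input; the built-in
fallback (:func:`joint_pca_embedding`) is a plain joint PCA after
per-group gene centering and is NOT a reimplementation of any
published batch integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from stimflow.io_core import ExpressionDataset


@dataclass
class ClusterLabeling:
    """Per-cell categorical labels with provenance."""

    labels: np.ndarray
    source: str  # "direct" or "transferred"
    vocabulary: list

    def __post_init__(self) -> None:
        if self.source not in ("direct", "transferred"):
            raise ValueError("source must be 'direct' or 'transferred'")
        extra = set(np.unique(self.labels)) - set(self.vocabulary)
        if extra:
            raise ValueError(f"labels outside vocabulary: {sorted(extra)}")


def cluster_control(
    dataset: ExpressionDataset,
    n_pcs: int = 10,
    k: int = 15,
    resolution: float = 0.8,
    seed: int = 0,
    n_comps: int = 50,
) -> ClusterLabeling:
    """Leiden clustering of the (control) dataset.

    PCA to ``n_comps`` components, a k-nearest-neighbor graph on the
    first ``n_pcs`` of them, then Leiden community detection at the
    given resolution.  Deterministic for a fixed seed.
    """
    n = dataset.n_cells
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the cell count {n}")
    X = dataset.dense()
    n_comps = min(n_comps, n - 1, X.shape[1])
    pca = PCA(n_components=n_comps, svd_solver="full", random_state=seed)
    pcs = pca.fit_transform(X)[:, : min(n_pcs, n_comps)]

    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    adj = nn.kneighbors_graph(mode="connectivity")
    adj = adj.maximum(adj.T)  # symmetrize
    sources, targets = adj.nonzero()
    edges = [(int(s), int(t)) for s, t in zip(sources, targets) if s < t]
    graph = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership, dtype=int)
    return ClusterLabeling(
        labels=labels, source="direct", vocabulary=sorted(set(labels.tolist()))
    )


def transfer_labels(
    embedding: np.ndarray,
    control_labels: ClusterLabeling,
    control_mask: np.ndarray,
    k: int = 15,
) -> ClusterLabeling:
    """Majority-vote label transfer from control cells to the rest.

    Each non-control cell adopts the most common label among its ``k``
    nearest control cells by Euclidean distance in ``embedding`` (rows
    cover all cells).  Ties are broken by the label of the single
    nearest neighbor carrying one of the tied labels.
    """
    embedding = np.asarray(embedding, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    if embedding.shape[0] != control_mask.shape[0]:
        raise ValueError("embedding and control_mask lengths differ")
    n_control = int(control_mask.sum())
    if n_control < k:
        raise ValueError(f"need at least k={k} control cells, got {n_control}")
    ctrl_emb = embedding[control_mask]
    ctrl_lab = np.asarray(control_labels.labels)
    if ctrl_lab.shape[0] != n_control:
        raise ValueError("control_labels length does not match control_mask")
    query = embedding[~control_mask]
    nn = NearestNeighbors(n_neighbors=k).fit(ctrl_emb)
    _, idx = nn.kneighbors(query)  # neighbors sorted by distance
    out = np.empty(query.shape[0], dtype=ctrl_lab.dtype)
    for i, neigh in enumerate(idx):
        neigh_labels = ctrl_lab[neigh]
        uniq, counts = np.unique(neigh_labels, return_counts=True)
        best = counts.max()
        tied = set(uniq[counts == best].tolist())
        if len(tied) == 1:
            out[i] = next(iter(tied))
        else:
            # nearest neighbor whose label is among the tied labels
            for lab in neigh_labels:
                if lab in tied:
                    out[i] = lab
                    break
    return ClusterLabeling(
        labels=out, source="transferred", vocabulary=list(control_labels.vocabulary)
    )


def joint_pca_embedding(
    dataset: ExpressionDataset,
    group_col: str,
    n_comps: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Fallback shared embedding: joint PCA after per-group gene centering.

    Subtracts each group's per-gene mean before a single PCA over all
    cells.  A plain stand-in for an externally computed integrated
    embedding, not a batch-integration method.
    """
    X = dataset.dense()
    groups = dataset.cell_meta[group_col].to_numpy()
    Xc = X.copy()
    for g in np.unique(groups):
        m = groups == g
        Xc[m] -= Xc[m].mean(axis=0)
    n_comps = min(n_comps, X.shape[0] - 1, X.shape[1])
    return PCA(n_components=n_comps, svd_solver="full", random_state=seed).fit_transform(
        Xc
    )
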