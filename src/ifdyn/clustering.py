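"""Jaccard-based substate clustering of interface contact sets.

Each pair of snapshots is compared through the Jaccard index of their
contact sets, J = |C1∩C2|/|C1∪C2|; hierarchical clustering (Ward.D2 on
the 1−J dissimilarity, via scipy's ward linkage which implements the
same Lance–Williams recurrence as R's hclust ward.D2) partitions the
trajectory into substates.  Diagnostics per candidate cluster count —
smallest/largest cluster size, number of label changes along time, and
mean within-cluster dissimilarity — codify the qualitative criteria
used to pick the substate count: substates should be well populated and
stable in time.

Note Ward linkage is applied to a non-Euclidean dissimilarity exactly
as practitioners do; merge heights are then heuristic, not variance
decompositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .contacts import ContactSet

__all__ = [
    "JaccardMatrix",
    "ClusterLabels",
    "jaccard",
    "jaccard_matrix",
    "cluster_interfaces",
    "suggest_n_clusters",
    "select_centroid",
    "pcoa_projection",
]


def jaccard(c1: ContactSet, c2: ContactSet, empty_empty: float = 1.0) -> float:
    """Jaccard index of two contact sets, in [0, 1].

    Two empty interfaces are identical by convention (1.0); pass
    ``empty_empty=0.0`` for the alternative convention.
    """
    u = len(c1.contacts | c2.contacts)
    if u == 0:
        return empty_empty
    return len(c1.contacts & c2.contacts) / u


@dataclass
class JaccardMatrix:
    """Symmetric snapshot × snapshot Jaccard similarity with times."""

    values: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        n = len(self.values)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if len(self.times) != n:
            raise ValueError("times length must match matrix size")

    @property
    def n(self) -> int:
        return len(self.values)

    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.values


@dataclass
class ClusterLabels:
    """Time-ordered substate assignment with diagnostics."""

    labels: np.ndarray  # integers in [1, n_clusters]
    n_clusters: int
    min_size: int = 0
    max_size: int = 0
    n_changes: int = 0
    centroids: dict[int, int] = field(default_factory=dict)  # cluster -> snapshot idx

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        sizes = np.bincount(self.labels)[1:]
        if len(sizes) != self.n_clusters or (sizes == 0).any():
            raise ValueError("labels must use every value in [1, n_clusters]")
        self.min_size = int(sizes.min())
        self.max_size = int(sizes.max())
        self.n_changes = int(np.sum(self.labels[1:] != self.labels[:-1]))

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def jaccard_matrix(
    series: list[ContactSet], empty_empty: float = 1.0
) -> JaccardMatrix:
    """Full pairwise Jaccard similarity over a contact-set series."""
    if len(series) < 2:
        raise ValueError("need at least 2 snapshots")
    n = len(series)
    vals = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = jaccard(series[i], series[j], empty_empty)
    times = np.array([cs.time for cs in series])
    return JaccardMatrix(values=vals, times=times)


def _ward_linkage(matrix: JaccardMatrix) -> np.ndarray:
    d = matrix.dissimilarity().copy()
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="ward")


def cluster_interfaces(matrix: JaccardMatrix, n_clusters: int) -> ClusterLabels:
    """Cut the Ward.D2 dendrogram of 1−J at ``n_clusters`` substates.

    Cluster ids are renumbered by order of first appearance along time,
    so label 1 is always the substate the trajectory starts in.
    """
    n = matrix.n
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    if n_clusters == 1:
        raw = np.ones(n, dtype=np.int64)
    else:
        raw = fcluster(_ward_linkage(matrix), t=n_clusters, criterion="maxclust")
        if len(np.unique(raw)) != n_clusters:
            # maxclust could not realise this k (tied heights); cut by height rank
            raise ValueError(
                f"dendrogram does not admit a cut into {n_clusters} clusters"
            )
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = np.array([remap[lab] for lab in raw], dtype=np.int64)
    cl = ClusterLabels(labels=labels, n_clusters=n_clusters)
    cl.centroids = {
        c: select_centroid(matrix, cl, c) for c in range(1, n_clusters + 1)
    }
    return cl


def suggest_n_clusters(
    matrix: JaccardMatrix,
    k_max: int = 6,
    min_size_frac: float = 0.05,
    changes_per_extra_cluster: int = 2,
) -> tuple[int, list[dict]]:
    """Diagnostics for k = 1..k_max and a recommended substate count.

    For each k the table reports the smallest and largest cluster size,
    the number of cluster changes along the trajectory and the mean
    within-cluster dissimilarity.  The recommended k is the largest one
    whose smallest cluster holds at least ``min_size_frac`` of the
    snapshots and whose label sequence changes at most
    ``changes_per_extra_cluster``·(k−1) times — i.e. all substates are
    well populated and long-lived.
    """
    if k_max < 2:
        raise ValueError("k_max must be ≥ 2")
    n = matrix.n
    diss = matrix.dissimilarity()
    rows: list[dict] = []
    recommended = 1
    for k in range(1, min(k_max, n) + 1):
        try:
            cl = cluster_interfaces(matrix, k)
        except ValueError:
            continue
        within = []
        for c in range(1, k + 1):
            m = cl.members(c)
            if len(m) > 1:
                sub = diss[np.ix_(m, m)]
                within.append(sub[np.triu_indices(len(m), 1)].mean())
            else:
                within.append(0.0)
        rows.append(
            {
                "k": k,
                "min_size": cl.min_size,
                "max_size": cl.max_size,
                "n_changes": cl.n_changes,
                "intra_cluster_dissimilarity": float(np.mean(within)),
            }
        )
        if cl.min_size >= min_size_frac * n and cl.n_changes <= (
            changes_per_extra_cluster * (k - 1)
        ):
            recommended = max(recommended, k)
    return recommended, rows


def select_centroid(
    matrix: JaccardMatrix, labels: ClusterLabels, cluster: int
) -> int:
    """Snapshot with the highest mean Jaccard similarity to its cluster.

    Singletons are their own centroid; ties break to the earliest time.
    """
    members = labels.members(cluster)
    if not len(members):
        raise ValueError(f"cluster {cluster} is empty")
    if len(members) == 1:
        return int(members[0])
    sub = matrix.values[np.ix_(members, members)]
    mean_sim = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
    best = members[mean_sim >= mean_sim.max() - 1e-12]
    return int(best[0])


def pcoa_projection(matrix: JaccardMatrix, n_dims: int = 2) -> np.ndarray:
    """Classical metric MDS (principal coordinates) of the 1−J distances.

    The squared dissimilarity matrix is double-centred; coordinates are
    the top eigenvectors scaled by the square root of their eigenvalues,
    with negative eigenvalues (non-Euclidean residual) truncated to 0.
    """
    n = matrix.n
    if n < n_dims + 1:
        raise ValueError("need at least n_dims + 1 snapshots")
    d2 = matrix.dissimilarity() ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1][:n_dims]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)
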