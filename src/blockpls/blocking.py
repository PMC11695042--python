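"""Gene-block discovery: k-means over variables and cluster-number selection.

Blocks are groups of correlated variables (genes).  Clustering treats each
of the p variables as a point in n-dimensional sample space, i.e. it runs on
the transposed (and by default autoscaled) data matrix.  Lloyd's algorithm
is used: points are assigned to the nearest centre by Euclidean distance and
centres are recomputed as cluster means, iterated to a fixed point.  The
number of blocks is chosen on a grid by maximizing the mean silhouette
index, with the total within-cluster sum of squares reported alongside as
an elbow diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io import Dataset, autoscale

__all__ = [
    "BlockPartition",
    "KSelectionReport",
    "kmeans_blocks",
    "total_within_ss",
    "silhouette_index",
    "choose_num_blocks",
    "cluster_variables",
]


@dataclass
class BlockPartition:
    """Assignment of p variables to C disjoint, non-empty blocks.

    ``labels`` holds block indices in 1..C (the convention used in all
    reports and CSV output).  ``centers`` is the C-by-d matrix of cluster
    centroids in sample space; it may be None for partitions supplied by the
    user rather than produced by clustering.
    """

    labels: np.ndarray
    centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.labels.size == 0:
            raise ValueError("empty partition")
        c = int(self.labels.max())
        if self.labels.min() < 1:
            raise ValueError("labels must be in 1..C")
        counts = np.bincount(self.labels, minlength=c + 1)[1:]
        if np.any(counts == 0):
            empty = int(np.argmin(counts)) + 1
            raise ValueError(f"block {empty} is empty")
        if self.centers is not None:
            self.centers = np.asarray(self.centers, dtype=float)
            if self.centers.shape[0] != c:
                raise ValueError("centers row count must equal block count")

    @property
    def n_blocks(self) -> int:
        return int(self.labels.max())

    @property
    def p(self) -> int:
        return self.labels.size

    @property
    def block_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_blocks + 1)[1:]

    def blocks(self) -> list[np.ndarray]:
        """Column-index arrays, one per block, in label order 1..C."""
        return [np.flatnonzero(self.labels == c + 1) for c in range(self.n_blocks)]

    @classmethod
    def from_labels(cls, labels, points: np.ndarray | None = None) -> "BlockPartition":
        labels = np.asarray(labels, dtype=int).ravel()
        centers = None
        if points is not None:
            points = np.asarray(points, dtype=float)
            c = int(labels.max())
            centers = np.vstack(
                [points[labels == k + 1].mean(axis=0) for k in range(c)]
            )
        return cls(labels=labels, centers=centers)

    @classmethod
    def single_block(cls, p: int) -> "BlockPartition":
        return cls(labels=np.ones(p, dtype=int))


@dataclass
class KSelectionReport:
    """Grid search over block counts: WSS and silhouette per K, chosen K."""

    k_grid: np.ndarray
    wss: np.ndarray
    silhouette: np.ndarray
    chosen_k: int

    def to_dict(self) -> dict:
        return {
            "k_grid": [int(k) for k in self.k_grid],
            "wss": [float(w) for w in self.wss],
            "silhouette": [float(s) for s in self.silhouette],
            "chosen_k": int(self.chosen_k),
        }


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centres by squared-distance sampling."""
    n = points.shape[0]
    centers = np.empty((k, points.shape[1]))
    first = int(rng.integers(n))
    centers[0] = points[first]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            # all remaining points coincide with a chosen centre
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers[j] = points[idx]
        d2 = np.minimum(d2, np.sum((points - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(
    points: np.ndarray, centers: np.ndarray, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd iterations to a fixed point; returns 0-based labels, centres, WSS trace.

    Assignment ties break to the lowest cluster index (argmin convention).
    An empty cluster is repaired by reseeding its centre at the point
    farthest from that point's current centre.
    """
    k = centers.shape[0]
    labels = None
    wss_trace: list[float] = []
    for _ in range(max_iter):
        d2 = cdist(points, centers, metric="sqeuclidean")
        new_labels = np.argmin(d2, axis=1)
        # repair empty clusters deterministically; a repair can empty the
        # donor cluster, so iterate until every cluster is populated
        for _ in range(k):
            empties = [c for c in range(k) if not np.any(new_labels == c)]
            if not empties:
                break
            for c in empties:
                far = int(np.argmax(d2[np.arange(points.shape[0]), new_labels]))
                centers[c] = points[far]
                d2[:, c] = np.sum((points - centers[c]) ** 2, axis=1)
                new_labels = np.argmin(d2, axis=1)
        wss_trace.append(float(d2[np.arange(points.shape[0]), new_labels].sum()))
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = labels == c
            if np.any(members):
                centers[c] = points[members].mean(axis=0)
    d2 = cdist(points, centers, metric="sqeuclidean")
    labels = np.argmin(d2, axis=1)
    wss_trace.append(float(d2[np.arange(points.shape[0]), labels].sum()))
    return labels, centers, wss_trace


def kmeans_blocks(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> BlockPartition:
    """Cluster p points (variables) into k blocks; best of ``n_restarts`` by WSS."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D (p, d) array")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > points.shape[0]:
        raise ValueError(f"k={k} exceeds number of points {points.shape[0]}")
    if np.isnan(points).any():
        raise ValueError("points contain missing values")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        centers = _kmeanspp_init(points, k, rng)
        labels, centers, trace = _lloyd(points, centers, max_iter=max_iter)
        wss = trace[-1]
        if best is None or wss < best[0]:
            best = (wss, labels, centers)
    _, labels, centers = best
    return BlockPartition(labels=labels + 1, centers=centers)


def total_within_ss(points: np.ndarray, partition: BlockPartition) -> float:
    """Total within-cluster sum of squares around the cluster means."""
    points = np.asarray(points, dtype=float)
    if partition.p != points.shape[0]:
        raise ValueError("partition does not match points")
    total = 0.0
    for c in range(partition.n_blocks):
        member = points[partition.labels == c + 1]
        mu = member.mean(axis=0)
        total += float(np.sum((member - mu) ** 2))
    return total


def silhouette_index(points: np.ndarray, partition: BlockPartition) -> float:
    """Mean silhouette over points: (b - a) / max(a, b), in [-1, 1].

    a is the mean distance to other members of the point's own cluster and
    b the smallest mean distance to another cluster.  Singleton clusters
    contribute 0.
    """
    points = np.asarray(points, dtype=float)
    c = partition.n_blocks
    if c < 2:
        raise ValueError("silhouette requires at least 2 blocks")
    labels = partition.labels
    d = cdist(points, points)
    sizes = partition.block_sizes
    scores = np.zeros(points.shape[0])
    # mean distance from every point to every cluster
    cluster_sums = np.vstack(
        [d[:, labels == k + 1].sum(axis=1) for k in range(c)]
    ).T  # (p, C)
    for i in range(points.shape[0]):
        own = labels[i] - 1
        if sizes[own] == 1:
            scores[i] = 0.0
            continue
        a = cluster_sums[i, own] / (sizes[own] - 1)
        b = np.inf
        for k in range(c):
            if k != own:
                b = min(b, cluster_sums[i, k] / sizes[k])
        m = max(a, b)
        scores[i] = 0.0 if m == 0 else (b - a) / m
    return float(scores.mean())


def choose_num_blocks(
    points: np.ndarray,
    k_grid,
    seed: int = 0,
    n_restarts: int = 10,
) -> KSelectionReport:
    """Evaluate WSS and silhouette over a K grid; choose the K maximizing silhouette.

    Ties break to the smaller K.  The WSS column is an elbow diagnostic and
    does not enter the choice.
    """
    k_grid = np.asarray(sorted(set(int(k) for k in np.atleast_1d(k_grid))))
    if k_grid.size == 0:
        raise ValueError("empty K grid")
    if k_grid.min() < 2:
        raise ValueError("K grid values must be >= 2")
    wss = np.empty(k_grid.size)
    sil = np.empty(k_grid.size)
    for i, k in enumerate(k_grid):
        part = kmeans_blocks(points, int(k), seed=seed + i, n_restarts=n_restarts)
        wss[i] = total_within_ss(points, part)
        sil[i] = silhouette_index(points, part)
    chosen = int(k_grid[int(np.argmax(sil))])
    return KSelectionReport(k_grid=k_grid, wss=wss, silhouette=sil, chosen_k=chosen)


def cluster_variables(
    ds: Dataset,
    k: int | None = None,
    k_grid=None,
    seed: int = 0,
    n_restarts: int = 10,
    scale: bool = True,
) -> tuple[BlockPartition, KSelectionReport | None]:
    """Cluster the variables of a Dataset into gene blocks.

    Points are the p columns of (by default autoscaled) X, viewed as points
    in n-dimensional genome space.  Either a fixed ``k`` or a ``k_grid`` to
    search must be given.
    """
    if (k is None) == (k_grid is None):
        raise ValueError("give exactly one of k or k_grid")
    work = autoscale(ds)[0] if scale else ds
    points = work.X.T
    report = None
    if k_grid is not None:
        report = choose_num_blocks(points, k_grid, seed=seed, n_restarts=n_restarts)
        k = report.chosen_k
    partition = kmeans_blocks(points, int(k), seed=seed, n_restarts=n_restarts)
    return partition, report
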