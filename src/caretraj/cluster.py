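"""Dissimilarity-based clustering and model selection.

Three candidate procedures operate directly on the precomputed OM distance
matrix: agglomerative clustering with complete linkage (the default),
agglomerative Ward (heuristic on a non-Euclidean dissimilarity; see docs),
and partitioning around medoids (PAM).  Partitions are scored by the average
silhouette width (ASW) and the retained solution is the largest cluster
count for which every cluster passes a minimum-size rule (about 1% of the
sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .om import DistanceMatrix

log = logging.getLogger(__name__)


@dataclass
class ClusterSolution:
    method: str
    k: int
    labels: np.ndarray  # 1..k, cluster 1 = largest
    sizes: np.ndarray
    asw: float
    asw_curve: dict[int, float] = field(default_factory=dict)
    size_threshold: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if self.sizes.sum() != len(self.labels):
            raise ValueError("cluster sizes do not sum to n")
        if not -1.0 <= self.asw <= 1.0:
            raise ValueError("average silhouette width outside [-1, 1]")


def agglomerate(dm: DistanceMatrix, method: str = "complete") -> np.ndarray:
    """Merge tree (scipy linkage encoding) on a precomputed dissimilarity.

    ``ward`` applies the standard Lance-Williams Ward update to the OM
    matrix even though it is not Euclidean; it is provided for comparison
    only and documented as heuristic.
    """
    if method not in ("complete", "ward"):
        raise ValueError(f"unknown linkage {method!r}")
    return linkage(dm.condensed(), method=method)


def _relabel_by_size(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Renumber labels so cluster 1 is the largest; ties by first appearance."""
    uniq, counts = np.unique(raw, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    mapping = {int(uniq[o]): rank + 1 for rank, o in enumerate(order)}
    labels = np.array([mapping[int(v)] for v in raw])
    return labels, counts[order]


def cut(tree: np.ndarray, k: int, dm: DistanceMatrix | None = None,
        method: str = "complete") -> ClusterSolution:
    """Partition into k clusters by severing the last k-1 merges."""
    n = tree.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    raw = fcluster(tree, t=k, criterion="maxclust")
    labels, sizes = _relabel_by_size(raw)
    asw = 0.0
    if dm is not None and len(np.unique(labels)) > 1:
        _, asw = silhouette(dm, labels)
    return ClusterSolution(method, int(labels.max()), labels, sizes, asw)


def silhouette(dm: DistanceMatrix, labels) -> tuple[np.ndarray, float]:
    """Per-point silhouette widths and their mean (ASW).

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean within-cluster
    distance (excluding self) and b(i) the smallest mean distance to another
    cluster.  Points in singleton clusters score 0 by convention.
    """
    labels = np.asarray(labels)
    d = dm.values
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = len(labels)
    masks = [labels == u for u in uniq]
    sizes = np.array([m.sum() for m in masks])
    # mean distance from every point to every cluster, (n, n_clusters)
    mean_to = np.stack([d[:, m].sum(axis=1) for m in masks], axis=1) / sizes
    s = np.zeros(n)
    for ci, m in enumerate(masks):
        if sizes[ci] == 1:
            continue  # singleton convention: s = 0
        a = mean_to[m, ci] * sizes[ci] / (sizes[ci] - 1)  # exclude self
        b = np.min(np.delete(mean_to[m], ci, axis=1), axis=1)
        s[m] = (b - a) / np.maximum(a, b)
    return s, float(s.mean())


def pam_medoids(dm: DistanceMatrix, k: int, seed: int = 0) -> ClusterSolution:
    """Partitioning around medoids (build + swap) on the dissimilarity.

    The build phase greedily picks medoids minimising total cost; the swap
    phase exchanges a medoid and a non-medoid while any exchange lowers the
    total distance to nearest medoids.  Deterministic given the matrix (the
    seed only breaks exact cost ties).
    """
    n = dm.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    rng = np.random.default_rng(seed)
    d = dm.values + rng.uniform(0, 1e-12, size=(n, n))  # tie-break jitter
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)

    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[:, None] - d, 0).sum(axis=0)
        gains[medoids] = -1
        m = int(np.argmax(gains))
        medoids.append(m)
        nearest = np.minimum(nearest, d[:, m])

    medoids = np.array(medoids)
    improved = True
    while improved:
        improved = False
        assign = d[:, medoids]
        cost = assign.min(axis=1).sum()
        for mi in range(k):
            others = np.setdiff1d(np.arange(n), medoids)
            for h in others:
                cand = medoids.copy()
                cand[mi] = h
                new_cost = d[:, cand].min(axis=1).sum()
                if new_cost < cost - 1e-12:
                    medoids, cost, improved = cand, new_cost, True
    raw = np.argmin(d[:, medoids], axis=1)
    labels, sizes = _relabel_by_size(raw)
    k_eff = int(labels.max())
    asw = silhouette(dm, labels)[1] if k_eff > 1 else 0.0
    return ClusterSolution("pam", k_eff, labels, sizes, asw)


def select_solution(
    tree: np.ndarray,
    dm: DistanceMatrix,
    k_range=range(2, 11),
    min_frac: float = 0.011,
    method: str = "complete",
) -> ClusterSolution:
    """Choose the cluster count under the minimum-size rule.

    Every k in ``k_range`` is scored by ASW (logged for inspection); the
    retained solution is the LARGEST k whose partition keeps all cluster
    sizes >= ceil(min_frac * n) — operationalising "all clusters contain at
    least ~1% of the participants".  Falls back to k=2 with a warning if no
    k qualifies.
    """
    ks = sorted(k_range)
    if not ks:
        raise ValueError("empty k range")
    n = dm.n
    threshold = int(np.ceil(min_frac * n))
    curve: dict[int, float] = {}
    feasible = []
    solutions = {}
    for k in ks:
        sol = cut(tree, k, dm, method=method)
        curve[k] = sol.asw
        solutions[k] = sol
        if sol.sizes.min() >= threshold and sol.k == k:
            feasible.append(k)
        log.info("k=%d: ASW=%.3f sizes=%s", k, sol.asw, sol.sizes.tolist())
    if feasible:
        best = solutions[max(feasible)]
    else:
        log.warning(
            "no k in %s satisfies the size rule (threshold %d); falling back to k=2",
            ks, threshold,
        )
        best = solutions.get(2) or cut(tree, 2, dm, method=method)
    best.asw_curve = curve
    best.size_threshold = threshold
    return best
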