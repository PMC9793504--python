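"""Optimal Matching (OM) edit distance between state sequences.

OM scores the minimum total cost of transforming one sequence into the other
by single-state substitutions and insertions/deletions (indels).  The
multichannel variant runs ONE dynamic programme on vector states, pooling
substitution costs across channels at each aligned position (local
interdependence) and pooling indel costs likewise.

The pairwise driver encodes every observed multichannel state as an integer,
precomputes the pooled substitution table over observed states only, and
runs a numba-compiled DP over all unordered pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .costs import CostModel, ext_index
from .model import Cohort

log = logging.getLogger(__name__)


def om_distance(a, b, sub: np.ndarray, indel: float) -> float:
    """OM distance between two single-channel sequences.

    ``a`` and ``b`` are sequences of row indices into the substitution
    matrix ``sub``; sequences may have unequal lengths.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    sub = np.asarray(sub, dtype=float)
    m = sub.shape[0]
    for seq in (a, b):
        if seq.size and (seq.min() < 0 or seq.max() >= m):
            raise ValueError("sequence state outside the cost-matrix alphabet")
    return float(_dp(a, b, sub, float(indel)))


@njit(cache=True)
def _dp(a, b, sub, indel):  # pragma: no cover - exercised via wrappers
    n, m = len(a), len(b)
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for u in range(m + 1):
        prev[u] = u * indel
    for t in range(1, n + 1):
        cur[0] = t * indel
        at = a[t - 1]
        for u in range(1, m + 1):
            best = prev[u - 1] + sub[at, b[u - 1]]
            alt = prev[u] + indel
            if alt < best:
                best = alt
            alt = cur[u - 1] + indel
            if alt < best:
                best = alt
            cur[u] = best
        prev, cur = cur, prev
    return prev[m]


def _pair_cost_matrix(x: np.ndarray, y: np.ndarray, cm: CostModel) -> np.ndarray:
    """(|x|, |y|) pooled substitution costs for two multichannel sequences."""
    cost = np.zeros((x.shape[0], y.shape[0]))
    for j, ch in enumerate(cm.channels):
        xi = np.array([ext_index(ch.spec, int(c)) for c in x[:, j]])
        yi = np.array([ext_index(ch.spec, int(c)) for c in y[:, j]])
        cost += ch.weight * ch.sub[np.ix_(xi, yi)]
    return cost


def multichannel_distance(x, y, cm: CostModel) -> float:
    """Multichannel OM distance between two (waves x channels) state arrays.

    States are cohort codes (ordinal levels >= 0, overlays negative).  With a
    single channel of weight 1 this reduces exactly to :func:`om_distance`.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.int64))
    y = np.atleast_2d(np.asarray(y, dtype=np.int64))
    if x.shape[1] != len(cm.channels) or y.shape[1] != len(cm.channels):
        raise ValueError("channel count does not match the cost model")
    cost = _pair_cost_matrix(x, y, cm)
    return float(_dp_costmat(cost, cm.pooled_indel))


@njit(cache=True)
def _dp_costmat(cost, indel):  # pragma: no cover - exercised via wrappers
    n, m = cost.shape
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for u in range(m + 1):
        prev[u] = u * indel
    for t in range(1, n + 1):
        cur[0] = t * indel
        for u in range(1, m + 1):
            best = prev[u - 1] + cost[t - 1, u - 1]
            alt = prev[u] + indel
            if alt < best:
                best = alt
            alt = cur[u - 1] + indel
            if alt < best:
                best = alt
            cur[u] = best
        prev, cur = cur, prev
    return prev[m]


@njit(cache=True)
def _pairwise_dp(codes, pooled, indel):  # pragma: no cover
    n, T = codes.shape
    out = np.zeros((n, n))
    prev = np.empty(T + 1)
    cur = np.empty(T + 1)
    for i in range(n):
        a = codes[i]
        for j in range(i + 1, n):
            b = codes[j]
            for u in range(T + 1):
                prev[u] = u * indel
            for t in range(1, T + 1):
                cur[0] = t * indel
                at = a[t - 1]
                for u in range(1, T + 1):
                    best = prev[u - 1] + pooled[at, b[u - 1]]
                    alt = prev[u] + indel
                    if alt < best:
                        best = alt
                    alt = cur[u - 1] + indel
                    if alt < best:
                        best = alt
                    cur[u] = best
                for u in range(T + 1):
                    prev[u] = cur[u]
            out[i, j] = prev[T]
            out[j, i] = prev[T]
    return out


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with its individual ids."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.values, checks=False)


def pairwise_distance_matrix(cohort: Cohort, cm: CostModel) -> DistanceMatrix:
    """Full multichannel OM distance matrix over a cohort.

    Each distinct multichannel person-wave state is encoded once and the
    pooled substitution table is computed over those codes, so the DP inner
    loop is a table lookup.
    """
    n, T, C = cohort.states.shape
    flat = cohort.states.reshape(n * T, C)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    codes = inverse.reshape(n, T).astype(np.int64)
    log.info("pairwise OM: n=%d, %d distinct multichannel states", n, len(uniq))

    pooled = np.zeros((len(uniq), len(uniq)))
    for j, ch in enumerate(cm.channels):
        idx = np.array([ext_index(ch.spec, int(c)) for c in uniq[:, j]])
        pooled += ch.weight * ch.sub[np.ix_(idx, idx)]

    values = _pairwise_dp(codes, pooled, cm.pooled_indel)
    log.info("pairwise OM: done (%d pairs)", n * (n - 1) // 2)
    return DistanceMatrix(list(cohort.ids), values)
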