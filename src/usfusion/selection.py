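"""Feature selection: CFS with best-first search, gain-ratio ranking, union.

Correlation-based feature selection (CFS) scores a feature subset S by
Hall's merit

    merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff),

where k = |S|, r_cf the mean feature-class correlation and r_ff the mean
feature-feature correlation, both measured as symmetric uncertainty on
discretized features.  The subset lattice is explored with best-first
search (backtracking, stop after 5 expansions without improvement).
Gain-ratio ranking keeps every feature whose information gain divided by
its split information exceeds a threshold (default 0.15).  The relevant
sets of the individual methods are combined by set union.

Continuous features are discretized by equal-frequency binning (10 bins
by default) before any entropy computation; ties everywhere break toward
the lowest feature index, so selections are deterministic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np


def discretize(X: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning of each column into integer codes."""
    X = np.asarray(X, dtype=float)
    out = np.zeros(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        col = X[:, j]
        edges = np.unique(np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1]))
        out[:, j] = np.searchsorted(edges, col, side="right")
    return out


def _entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_entropy(a: np.ndarray, b: np.ndarray) -> float:
    amax = int(a.max()) + 1
    return _entropy(a.astype(np.int64) * (int(b.max()) + 1) + b)


def information_gain(a: np.ndarray, b: np.ndarray) -> float:
    """I(A; B) = H(A) + H(B) - H(A, B), in bits."""
    return _entropy(a) + _entropy(b) - _joint_entropy(a, b)


def symmetric_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """2 I(A;B) / (H(A) + H(B)), in [0, 1]; 0 when both are constant."""
    ha, hb = _entropy(a), _entropy(b)
    if ha + hb <= 0:
        return 0.0
    return float(np.clip(2.0 * information_gain(a, b) / (ha + hb), 0.0, 1.0))


@dataclass
class SelectionResult:
    """Selected feature indices with their scores."""

    method: str
    selected: list
    scores: dict
    n_features: int


class _CfsCache:
    """Memoized symmetric-uncertainty correlations for one dataset."""

    def __init__(self, Xd: np.ndarray, y_codes: np.ndarray):
        self.Xd = Xd
        self.y = y_codes
        self.m = Xd.shape[1]
        self._cf = np.full(self.m, np.nan)
        self._ff: dict[tuple[int, int], float] = {}

    def cf(self, i: int) -> float:
        if np.isnan(self._cf[i]):
            self._cf[i] = symmetric_uncertainty(self.Xd[:, i], self.y)
        return float(self._cf[i])

    def ff(self, i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in self._ff:
            self._ff[key] = symmetric_uncertainty(self.Xd[:, key[0]],
                                                  self.Xd[:, key[1]])
        return self._ff[key]

    def merit(self, subset) -> float:
        k = len(subset)
        if k == 0:
            raise ValueError("merit of the empty subset is undefined")
        r_cf = float(np.mean([self.cf(i) for i in subset]))
        if k == 1:
            return r_cf
        pairs = [(a, b) for ai, a in enumerate(subset) for b in subset[ai + 1:]]
        r_ff = float(np.mean([self.ff(a, b) for a, b in pairs]))
        denom = np.sqrt(k + k * (k - 1) * r_ff)
        return float(k * r_cf / denom) if denom > 0 else 0.0


def _prepare(X: np.ndarray, y, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    _, y_codes = np.unique(np.asarray(y), return_inverse=True)
    if len(np.unique(y_codes)) < 2:
        raise ValueError("selection needs at least two classes")
    return discretize(X, n_bins), y_codes


def cfs_merit(subset, X: np.ndarray, y, n_bins: int = 10) -> float:
    """Hall's CFS merit of a feature-index subset against the class."""
    Xd, y_codes = _prepare(X, y, n_bins)
    return _CfsCache(Xd, y_codes).merit(sorted(subset))


def best_first_cfs(X: np.ndarray, y, n_bins: int = 10,
                   stale_limit: int = 5) -> SelectionResult:
    """Best-first search over feature subsets maximizing the CFS merit.

    Starts from the empty set, always expands the best unexpanded subset
    by one feature, and stops after ``stale_limit`` expansions that fail
    to improve the best merit found; ties break toward the subset that is
    lexicographically smallest in feature indices.
    """
    Xd, y_codes = _prepare(X, y, n_bins)
    cache = _CfsCache(Xd, y_codes)
    m = cache.m
    best_subset: tuple = ()
    best_merit = -np.inf
    # heap of (-merit, subset); sorted index tuples break ties lexicographically
    open_heap: list = [(0.0, ())]
    visited = {frozenset()}
    stale = 0
    while open_heap and stale < stale_limit:
        _, subset = heapq.heappop(open_heap)
        improved = False
        for j in range(m):
            if j in subset:
                continue
            child = tuple(sorted(subset + (j,)))
            key = frozenset(child)
            if key in visited:
                continue
            visited.add(key)
            merit = cache.merit(child)
            if merit > best_merit + 1e-12:
                best_merit, best_subset = merit, child
                improved = True
            heapq.heappush(open_heap, (-merit, child))
        stale = 0 if improved else stale + 1
    scores = {"merit": best_merit}
    return SelectionResult(method="cfs", selected=list(best_subset),
                           scores=scores, n_features=m)


def gain_ratio(feature_codes: np.ndarray, y_codes: np.ndarray) -> float:
    """Information gain of the class over split information of the feature."""
    split_info = _entropy(feature_codes)
    if split_info <= 0:
        return 0.0
    return float(information_gain(y_codes, feature_codes) / split_info)


def gain_ratio_rank(X: np.ndarray, y, threshold: float = 0.15,
                    n_bins: int = 10) -> SelectionResult:
    """Rank features by gain ratio; keep those scoring above ``threshold``."""
    Xd, y_codes = _prepare(X, y, n_bins)
    ratios = np.array([gain_ratio(Xd[:, j], y_codes)
                       for j in range(Xd.shape[1])])
    order = np.lexsort((np.arange(len(ratios)), -ratios))
    selected = [int(j) for j in order if ratios[j] > threshold]
    return SelectionResult(method="gain_ratio", selected=selected,
                           scores={int(j): float(ratios[j])
                                   for j in range(len(ratios))},
                           n_features=Xd.shape[1])


def union_relevant(*results: SelectionResult) -> SelectionResult:
    """Set union of selections, ordered by original feature index."""
    if not results:
        raise ValueError("at least one selection result required")
    spaces = {r.n_features for r in results}
    if len(spaces) != 1:
        raise ValueError("selections cover different feature spaces")
    merged = sorted(set().union(*(r.selected for r in results)))
    return SelectionResult(method="union", selected=[int(j) for j in merged],
                           scores={}, n_features=results[0].n_features)
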