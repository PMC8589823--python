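"""Exact penalized change-point detection on representation traces.

Implements PELT (pruned exact linear time) with a kernelized mean-change
segment cost: for a segment I, cost(I) = sum_t k(x_t, x_t) -
(1/|I|) * sum_{t,u in I} k(x_t, x_u).  With the linear kernel this is the
within-segment sum of squared deviations from the segment mean; the RBF
kernel (median-heuristic bandwidth by default) detects changes in the full
distribution.  The pruning step never discards an optimal candidate because
the kernel cost is subadditive, so PELT returns the same optimum as
unpruned optimal partitioning.

A penalty-calibration routine exploits the monotone non-increase of the
detected change-point count in the penalty to hit a target average count
(tuning for roughly ten robust change points per trajectory keeps any
manual review workload bounded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator


@dataclass
class CPResult:
    """Sorted internal segment-start indices and the penalized objective."""

    changepoints: list[int]
    total_cost: float


@dataclass
class CalibrationResult:
    penalty: float
    achieved_mean: float
    status: str  # "ok", "warning_unachievable", "closest"


def _as_trace(trace) -> np.ndarray:
    x = np.asarray(trace, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("trace must be a non-empty (tau, width) array")
    return x


def standardize_trace(trace) -> np.ndarray:
    """Per-channel zero mean / unit variance over the trajectory."""
    x = _as_trace(trace).copy()
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def median_bandwidth(x: np.ndarray, max_points: int = 500) -> float:
    """Median pairwise distance heuristic for the RBF bandwidth."""
    if x.shape[0] > max_points:
        idx = np.linspace(0, x.shape[0] - 1, max_points).astype(int)
        x = x[idx]
    d = pdist(x)
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return float(med) if med > 0 else 1.0


class _CostCache:
    """O(1) segment costs from prefix sums (linear) or Gram prefix sums (rbf)."""

    def __init__(self, x: np.ndarray, kernel: str, bandwidth: float | None):
        self.n = x.shape[0]
        self.kernel = kernel
        if kernel == "linear":
            self.s1 = np.vstack([np.zeros(x.shape[1]), np.cumsum(x, axis=0)])
            self.s2 = np.concatenate([[0.0], np.cumsum((x**2).sum(axis=1))])
        elif kernel == "rbf":
            bw = median_bandwidth(x) if bandwidth is None else float(bandwidth)
            if bw <= 0:
                raise ValueError("rbf bandwidth must be positive")
            G = np.exp(-squareform(pdist(x, "sqeuclidean")) / (2.0 * bw * bw))
            np.fill_diagonal(G, 1.0)
            P = np.zeros((self.n + 1, self.n + 1))
            P[1:, 1:] = G.cumsum(axis=0).cumsum(axis=1)
            self.P = P
        else:
            raise ValueError(f"unknown kernel {kernel!r}")

    def cost(self, start: int, end: int) -> float:
        if not 0 <= start < end <= self.n:
            raise ValueError(f"invalid segment [{start}, {end})")
        n = end - start
        if self.kernel == "linear":
            ssq = self.s2[end] - self.s2[start]
            mean_part = ((self.s1[end] - self.s1[start]) ** 2).sum() / n
            return float(max(ssq - mean_part, 0.0))
        block = (
            self.P[end, end] - self.P[start, end] - self.P[end, start] + self.P[start, start]
        )
        return float(max(n - block / n, 0.0))

    def cost_vector(self, starts: np.ndarray, end: int) -> np.ndarray:
        n = end - starts
        if self.kernel == "linear":
            ssq = self.s2[end] - self.s2[starts]
            mean_part = ((self.s1[end] - self.s1[starts]) ** 2).sum(axis=1) / n
            return np.maximum(ssq - mean_part, 0.0)
        block = (
            self.P[end, end] - self.P[starts, end] - self.P[end, starts] + self.P[starts, starts]
        )
        return np.maximum(n - block / n, 0.0)


def segment_cost(trace, start: int, end: int, kernel: str = "linear", bandwidth=None) -> float:
    """Kernelized mean-change cost of the half-open segment [start, end)."""
    x = _as_trace(trace)
    return _CostCache(x, kernel, bandwidth).cost(start, end)


class KernelCPD(BaseEstimator):
    """PELT change-point detector with a kernel mean-change cost.

    Parameters
    ----------
    kernel : {"linear", "rbf"}
    bandwidth : float or None
        RBF bandwidth; None uses the median heuristic.
    penalty : float
        Nonnegative cost added per change point.
    min_segment : int
        Minimum segment length in frames (default 2, i.e. one second at the
        2 fps frame rate: suppresses single-frame segments).
    standardize : bool
        Standardize each channel over the trajectory before costing.
    """

    def __init__(self, kernel="linear", bandwidth=None, penalty=1.0, min_segment=2,
                 standardize=True):
        self.kernel = kernel
        self.bandwidth = bandwidth
        self.penalty = penalty
        self.min_segment = min_segment
        self.standardize = standardize

    def fit(self, X, y=None):
        x = _as_trace(X)
        if self.penalty < 0:
            raise ValueError("penalty must be nonnegative")
        if self.min_segment < 1:
            raise ValueError("min_segment must be >= 1")
        T = x.shape[0]
        if T < self.min_segment:
            raise ValueError(f"trace length {T} shorter than min_segment {self.min_segment}")
        if self.standardize:
            x = standardize_trace(x)
        cache = _CostCache(x, self.kernel, self.bandwidth)
        beta = float(self.penalty)
        msl = int(self.min_segment)

        # F[t]: optimal objective of frames [0, t) plus beta; PELT recursion.
        # Pruning is delayed by min_segment frames: when candidate s is
        # dominated at time u (F[s] + c(s, u) > F[u]), the dominating path
        # through u only becomes admissible at u + msl, so s stays usable
        # until then.  With msl == 1 this reduces to standard PELT pruning.
        F = np.full(T + 1, np.inf)
        F[0] = -beta
        prev = np.zeros(T + 1, dtype=np.int64)
        expiry: dict[int, float] = {0: np.inf}
        for t in range(msl, T + 1):
            s_new = t - msl
            if s_new > 0 and np.isfinite(F[s_new]):
                expiry[s_new] = np.inf
            for s in [s for s, e in expiry.items() if e <= t]:
                del expiry[s]
            starts = np.fromiter(sorted(expiry), dtype=np.int64)
            vals = F[starts] + cache.cost_vector(starts, t) + beta
            k = int(np.argmin(vals))
            F[t] = vals[k]
            prev[t] = starts[k]
            for s, val in zip(starts, vals):
                if val - beta > F[t] and expiry[int(s)] == np.inf:
                    expiry[int(s)] = t + msl

        cps = []
        t = T
        while t > 0:
            s = int(prev[t])
            if s > 0:
                cps.append(s)
            t = s
        cps.reverse()
        self.changepoints_ = cps
        self.total_cost_ = float(F[T])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).changepoints_


def pelt(trace, penalty: float, kernel: str = "linear", bandwidth=None,
         min_segment: int = 2, standardize: bool = True) -> CPResult:
    """Exact penalized segmentation of a representation trace."""
    est = KernelCPD(kernel=kernel, bandwidth=bandwidth, penalty=penalty,
                    min_segment=min_segment, standardize=standardize).fit(trace)
    return CPResult(changepoints=est.changepoints_, total_cost=est.total_cost_)


def calibrate_penalty(
    traces,
    target_mean: float,
    kernel: str = "linear",
    bandwidth=None,
    min_segment: int = 2,
    standardize: bool = True,
    tol: float = 0.5,
    max_iter: int = 60,
) -> CalibrationResult:
    """Penalty whose mean change-point count over `traces` hits target_mean.

    Binary search using the monotone non-increase of the count in the
    penalty; returns the closest achievable penalty if the step function
    never lands within ``tol`` of the target.
    """
    if target_mean < 0:
        raise ValueError("target_mean must be nonnegative")
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")

    def mean_count(pen: float) -> float:
        return float(
            np.mean(
                [
                    len(
                        pelt(tr, pen, kernel=kernel, bandwidth=bandwidth,
                             min_segment=min_segment, standardize=standardize).changepoints
                    )
                    for tr in traces
                ]
            )
        )

    c0 = mean_count(0.0)
    if target_mean > c0 + tol:
        return CalibrationResult(0.0, c0, "warning_unachievable")
    hi = 1.0
    while mean_count(hi) > target_mean and hi < 1e12:
        hi *= 4.0
    lo = 0.0
    best = (hi, mean_count(hi))
    if abs(best[1] - target_mean) <= tol:
        return CalibrationResult(best[0], best[1], "ok")
    if abs(c0 - target_mean) <= tol:
        return CalibrationResult(0.0, c0, "ok")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c = mean_count(mid)
        if abs(c - target_mean) <= tol:
            return CalibrationResult(mid, c, "ok")
        if abs(c - target_mean) < abs(best[1] - target_mean):
            best = (mid, c)
        if c > target_mean:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(best[0], best[1], "closest")
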