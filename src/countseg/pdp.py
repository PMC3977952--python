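"""Pruned dynamic programming for exact multiple change-point detection.

The segmentation model: a series ``y_1..y_n`` is piecewise distributed, each
segment ``r`` carrying its own parameter ``theta_r`` under a one-parameter
convex loss (see :mod:`countseg.losses`).  The optimal cost in ``k``
segments obeys the recursion

    C[k, t] = min_{tau} ( C[k-1, tau] + min_theta c((tau, t], theta) )

The pruned sweep permutes the two minimizations: every candidate last
change-point ``tau`` keeps the interval of ``theta`` values ("live set") on
which it is not yet dominated; a candidate whose live set empties is
discarded forever.  The result is exact — identical costs to the unpruned
quadratic DP — at near-linear empirical cost in ``n``.

Two implementations coexist: an instrumentable pure-Python sweep
(:func:`sweep_step` / ``engine="python"``) and a compiled kernel
(:mod:`countseg._pdp_numba`, the default engine).  :func:`naive_dp` is the
unpruned quadratic oracle used to pin both down in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _pdp_numba
from .compression import PlateauMap, compress, map_breakpoints_to_original
from .losses import LossModel, SegmentCostAccumulator

__all__ = [
    "Candidate",
    "SegmentationResult",
    "pdp_pass",
    "sweep_step",
    "backtrack",
    "naive_dp",
    "best_segmentation_with_breakpoint",
]

_FAMILY_CODE = {"nbinom": 0, "poisson": 1, "gaussian": 2}
_REL_TIE = 1e-10


@dataclass
class Candidate:
    """A last-change-point candidate during the sweep at one level ``k``.

    ``tau`` is the number of points before the last segment (1-based
    inclusive end of segment ``k-1``); ``constant`` is ``C[k-1, tau]``;
    ``acc`` accumulates the cost of points ``tau+1..t``; ``live`` is the
    interval of ``theta`` on which the candidate is not yet dominated
    (``None`` once pruned).
    """

    tau: int
    constant: float
    acc: SegmentCostAccumulator
    live: tuple[float, float] | None


def _constrained_min(cand: Candidate) -> float:
    th = cand.acc.argmin()
    lo, hi = cand.live
    th = min(max(th, lo), hi)
    return cand.constant + cand.acc.cost(th)


def sweep_step(
    candidates: list[Candidate],
    y: float,
    w: float,
    new_constant: float,
    model: LossModel,
    new_tau: int | None = None,
) -> tuple[list[Candidate], float, int]:
    """One step of the functional-pruning sweep at a fixed level ``k``.

    Folds the new point into every candidate, takes the running minimum
    over live sets, then prunes each candidate against the entering
    candidate's constant ``new_constant = C[k-1, t]`` and hands the
    uncovered parameter region to the entering candidate (pruned on entry
    when empty).  Pass ``new_tau=None`` at the final position to skip entry.

    Returns ``(surviving candidates, C[k, t], argmin tau)``.
    """
    from .losses import level_set

    for cand in candidates:
        cand.acc.add(y, w)
    vals = [_constrained_min(c) for c in candidates]
    best = min(vals)
    tie = best + _REL_TIE * max(1.0, abs(best))
    arg = next(c.tau for c, v in zip(candidates, vals) if v <= tie)

    if new_tau is None:
        return candidates, best, arg

    survivors: list[Candidate] = []
    for cand in candidates:
        ls = level_set(cand.acc, cand.constant, new_constant)
        if ls is None:
            cand.live = None
            continue
        lo = max(cand.live[0], ls[0])
        hi = min(cand.live[1], ls[1])
        if lo <= hi:
            cand.live = (lo, hi)
            survivors.append(cand)
        else:
            cand.live = None

    dlo, dhi = model.clipped_space
    gaps = _complement(sorted((c.live for c in survivors)), dlo, dhi)
    if gaps:
        hull = (gaps[0][0], gaps[-1][1])
        survivors.append(
            Candidate(new_tau, new_constant, SegmentCostAccumulator(model), hull)
        )
    return survivors, best, arg


def _complement(intervals, dlo, dhi, gap_tol=4e-9):
    """Gaps of a union of sorted intervals within [dlo, dhi]."""
    gaps = []
    cover = dlo
    for lo, hi in intervals:
        if lo > cover + gap_tol:
            gaps.append((cover, lo))
        cover = max(cover, hi)
    if cover < dhi - gap_tol:
        gaps.append((cover, dhi))
    return gaps


@dataclass
class SegmentationResult:
    """Optimal costs, backpointers and breakpoints for all ``k <= kmax``.

    Costs and backpointers are stored in effective (possibly compressed)
    coordinates; breakpoints are reported in original coordinates as
    1-based inclusive segment ends.
    """

    model: LossModel
    kmax: int
    costs: np.ndarray  # (kmax+1, m+1); costs[k, t] = C_{k,t}
    backpointers: np.ndarray  # (kmax+1, m+1) int
    y: np.ndarray  # effective values
    w: np.ndarray  # effective weights
    pmap: PlateauMap | None = None  # set when the series was compressed
    live_trace: list | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        """Original series length (sum of weights)."""
        return int(round(self.w.sum()))

    @property
    def m(self) -> int:
        """Effective (compressed) number of points."""
        return len(self.y)

    @property
    def optimal_costs(self) -> np.ndarray:
        """C_{k,n} for k = 1..kmax."""
        return self.costs[1:, self.m]

    def breakpoints(self, k: int, original: bool = True) -> np.ndarray:
        """The ``k-1`` change-points of the optimal ``k``-segmentation."""
        bc = backtrack(self, k)
        if original and self.pmap is not None:
            return map_breakpoints_to_original(bc, self.pmap)
        return bc

    def segment_bounds(self, k: int, original: bool = True) -> np.ndarray:
        """(k, 2) array of 1-based inclusive [start, end] per segment."""
        n = self.n if (original and self.pmap is not None) else self.m
        br = self.breakpoints(k, original=original)
        edges = np.concatenate(([0], br, [n]))
        return np.column_stack((edges[:-1] + 1, edges[1:]))

    def theta_hat(self, k: int) -> np.ndarray:
        """Per-segment parameter estimates for the optimal ``k``-segmentation."""
        out = np.empty(k)
        for i, (a, b) in enumerate(self.segment_bounds(k, original=False)):
            acc = SegmentCostAccumulator(self.model)
            for t in range(a - 1, b):
                acc.add(float(self.y[t]), float(self.w[t]))
            out[i] = acc.argmin()
        return out

    def segment_means(self, k: int) -> np.ndarray:
        """Per-segment weighted mean counts."""
        out = np.empty(k)
        for i, (a, b) in enumerate(self.segment_bounds(k, original=False)):
            sl = slice(a - 1, b)
            out[i] = np.average(self.y[sl], weights=self.w[sl])
        return out


def pdp_pass(
    series,
    model: LossModel,
    kmax: int,
    weights=None,
    use_compression: bool | None = None,
    engine: str = "numba",
    record_live_sets: bool = False,
) -> SegmentationResult:
    """Run the pruned DP sweep, returning exact ``C[k, t]`` for ``k <= kmax``.

    Parameters
    ----------
    series : array-like
        Counts (non-negative integers for the count families).
    model : LossModel
    kmax : int
        Largest number of segments; must not exceed the effective length.
    weights : array-like, optional
        Pre-weighted input (e.g. from bedGraph intervals); disables the
        internal compression step.
    use_compression : bool, optional
        Plateau-compress before the sweep.  Default: on for unweighted
        input (lossless for the optimal costs), off when weights are given.
    engine : {"numba", "python"}
        Compiled kernel (default) or instrumentable reference sweep.
    record_live_sets : bool
        With ``engine="python"``, record every step's candidate live sets
        in ``result.live_trace`` (for diagnostics/tests).
    """
    y = np.asarray(series, dtype=np.float64)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("series must be a non-empty 1-d array")
    if model.family != "gaussian":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("count losses require non-negative integer counts")

    pmap = None
    if weights is not None:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != y.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match the series")
    elif use_compression or use_compression is None:
        pmap = compress(y)
        if len(pmap) == len(y):  # nothing to gain
            pmap = None
            w = np.ones_like(y)
        else:
            y = pmap.values.astype(np.float64)
            w = pmap.weights.astype(np.float64)
    else:
        w = np.ones_like(y)

    m = len(y)
    if not (1 <= kmax <= m):
        raise ValueError(
            f"kmax={kmax} must lie in [1, {m}] (effective series length)"
        )

    if engine == "numba":
        C, BP = _pdp_numba.pdp_sweep(y, w, float(model.phi), _FAMILY_CODE[model.family], kmax)
        trace = None
    elif engine == "python":
        C, BP, trace = _python_sweep(y, w, model, kmax, record_live_sets)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    return SegmentationResult(model, kmax, C, BP, y, w, pmap, trace)


def _python_sweep(y, w, model, kmax, record):
    m = len(y)
    C = np.full((kmax + 1, m + 1), np.inf)
    BP = np.zeros((kmax + 1, m + 1), dtype=np.int64)
    C[0, 0] = 0.0
    acc = SegmentCostAccumulator(model)
    for t in range(1, m + 1):
        acc.add(float(y[t - 1]), float(w[t - 1]))
        C[1, t] = acc.min_value()
    trace = [] if record else None
    for k in range(2, kmax + 1):
        cands = [
            Candidate(k - 1, C[k - 1, k - 1], SegmentCostAccumulator(model), model.clipped_space)
        ]
        for t in range(k, m + 1):
            new_tau = t if t < m else None
            cands, C[k, t], BP[k, t] = sweep_step(
                cands, float(y[t - 1]), float(w[t - 1]), C[k - 1, t], model, new_tau
            )
            if record:
                trace.append((k, t, [(c.tau, c.live) for c in cands]))
    return C, BP, trace


def backtrack(result: SegmentationResult, k: int) -> np.ndarray:
    """Recover the ``k-1`` change-points (effective coordinates) of ``M_{k,n}``."""
    if not (1 <= k <= result.kmax):
        raise ValueError(f"k={k} outside [1, kmax={result.kmax}]")
    breaks = []
    t = result.m
    for level in range(k, 1, -1):
        t = int(result.backpointers[level, t])
        breaks.append(t)
    return np.array(breaks[::-1], dtype=np.int64)


def naive_dp(series, model: LossModel, kmax: int, weights=None) -> np.ndarray:
    """Unpruned O(kmax * m^2) dynamic program — the exactness oracle.

    Returns the full cost matrix ``C[k, t]`` (shape ``(kmax+1, m+1)``,
    ``inf`` where infeasible), computed from a precomputed table of
    single-segment optimal costs.  Quadratic: keep ``m`` small.
    """
    y = np.asarray(series, dtype=np.float64)
    m = len(y)
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=np.float64)
    if not (1 <= kmax <= m):
        raise ValueError("kmax out of range")

    # seg[i, j] = optimal cost of segment covering points i+1..j (1-based j)
    seg = np.full((m, m + 1), np.inf)
    for i in range(m):
        acc = SegmentCostAccumulator(model)
        for j in range(i + 1, m + 1):
            acc.add(float(y[j - 1]), float(w[j - 1]))
            seg[i, j] = acc.min_value()

    C = np.full((kmax + 1, m + 1), np.inf)
    C[0, 0] = 0.0
    C[1, 1:] = seg[0, 1:]
    for k in range(2, kmax + 1):
        for t in range(k, m + 1):
            best = np.inf
            for tau in range(k - 1, t):
                v = C[k - 1, tau] + seg[tau, t]
                if v < best:
                    best = v
            C[k, t] = best
    return C


def best_segmentation_with_breakpoint(
    series, model: LossModel, K: int, j: int, t: int, weights=None
) -> tuple[np.ndarray, float]:
    """Optimal ``K``-segmentation constrained to have its ``j``-th change-point at ``t``.

    Decomposes as a forward pass on points ``1..t`` in ``j`` segments plus a
    backward pass (reversed series) on points ``t+1..n`` in ``K-j`` segments.
    Minimizing the returned cost over ``t`` recovers the unconstrained
    ``C_{K,n}``.  Positions are in effective coordinates of the input as
    given (no compression is applied here, so constrained positions mean
    what the caller thinks they mean).
    """
    y = np.asarray(series, dtype=np.float64)
    n = len(y)
    if not (1 <= j <= K - 1):
        raise ValueError(f"j={j} must lie in [1, K-1={K - 1}]")
    if not (j <= t <= n - (K - j)):
        raise ValueError(f"breakpoint position t={t} infeasible for j={j}, K={K}, n={n}")
    w = None if weights is None else np.asarray(weights, dtype=np.float64)

    fwd = pdp_pass(y[:t], model, j, weights=None if w is None else w[:t], use_compression=False)
    bwd = pdp_pass(
        y[t:][::-1], model, K - j,
        weights=None if w is None else w[t:][::-1], use_compression=False,
    )
    cost = fwd.costs[j, t] + bwd.costs[K - j, n - t]
    left = fwd.breakpoints(j, original=False)
    right_rev = bwd.breakpoints(K - j, original=False)
    right = t + np.sort((n - t) - right_rev)
    breaks = np.concatenate((left, [t], right)).astype(np.int64)
    return np.unique(breaks), float(cost)
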