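"""Global negative binomial overdispersion estimation.

The dispersion ``phi`` is assumed common to all segments.  It is estimated
by the moment identity ``phi = E(Y)^2 / (Var(Y) - E(Y))`` evaluated on
every sliding window of width ``h`` (stride 1), taking the median of the
finite window estimates.  Windows straddling change-points bias individual
estimates, which is what the median is there to absorb.  When the median
is non-positive (common for near-Poisson data, where window estimates
straddle +/- infinity) the window is doubled and the procedure repeated;
past ``h > n/2`` it falls back to the whole-series moment estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DispersionEstimate", "DispersionError", "window_moment_estimate", "estimate_phi"]


class DispersionError(RuntimeError):
    """No positive dispersion estimate could be obtained."""


@dataclass(frozen=True)
class DispersionEstimate:
    """Result of the windowed-median moment estimation of ``phi``."""

    phi_hat: float
    window_used: int
    n_windows: int
    trace: list[tuple[int, float]] = field(default_factory=list)

    def __float__(self) -> float:
        return self.phi_hat


def window_moment_estimate(window) -> float:
    """Moment estimate ``mean^2 / (var - mean)`` on one window.

    Uses the unbiased (h-1 divisor) variance.  May be negative (apparent
    under-dispersion) or non-finite (variance equal to the mean); callers
    are expected to filter.
    """
    x = np.asarray(window, dtype=np.float64)
    if x.size < 2:
        raise ValueError("window must contain at least 2 points")
    m = x.mean()
    v = x.var(ddof=1)
    denom = v - m
    if denom == 0.0:
        return np.inf if m > 0 else np.nan
    return m * m / denom


def _sliding_estimates(y: np.ndarray, h: int) -> np.ndarray:
    """All stride-1 window moment estimates via cumulative sums (O(n))."""
    n = len(y)
    c1 = np.concatenate(([0.0], np.cumsum(y)))
    c2 = np.concatenate(([0.0], np.cumsum(y * y)))
    s1 = c1[h:] - c1[:-h]
    s2 = c2[h:] - c2[:-h]
    mean = s1 / h
    var = (s2 - h * mean * mean) / (h - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = mean * mean / (var - mean)
    return est[(n - h + 1) * 0:]  # length n-h+1


def estimate_phi(series, h0: int = 15) -> DispersionEstimate:
    """Estimate ``phi`` by the windowed-median moment procedure.

    Starts at window width ``h0`` (default 15) and doubles the width until
    the median of the finite window estimates is positive; falls back to
    the whole-series moment estimate once ``h`` would exceed ``n/2``.

    Raises
    ------
    DispersionError
        If even the whole-series estimate is non-positive (e.g. a constant
        or under-dispersed series): supply ``phi`` explicitly.
    """
    y = np.asarray(series, dtype=np.float64)
    n = len(y)
    if n < h0:
        raise ValueError(f"series of length {n} shorter than initial window h0={h0}")
    trace: list[tuple[int, float]] = []
    h = h0
    while h <= n // 2:
        est = _sliding_estimates(y, h)
        finite = est[np.isfinite(est)]
        med = float(np.median(finite)) if finite.size else float("nan")
        trace.append((h, med))
        if np.isfinite(med) and med > 0:
            return DispersionEstimate(med, h, len(est), trace)
        h *= 2
    glob = window_moment_estimate(y)
    trace.append((n, glob))
    if np.isfinite(glob) and glob > 0:
        return DispersionEstimate(float(glob), n, 1, trace)
    raise DispersionError(
        "no positive dispersion estimate could be obtained from the data; "
        "the series may be under-dispersed or constant — supply phi explicitly"
    )
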