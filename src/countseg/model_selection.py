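"""Choosing the number of segments.

The main tool is a non-asymptotic "oracle" penalty: the criterion for ``K``
segments is the optimal segmentation cost plus

    beta * K * (1 + 4 * sqrt(1.1 + log(n / K)))**2

whose constant ``beta`` must be calibrated on the data.  Calibration uses
the slope heuristic: at large ``K`` (past the true number of segments) the
optimal cost decreases approximately linearly in the penalty shape; the
fitted slope ``s`` identifies the minimal penalty, and ``beta = 2 * |s|``
(the "twice the minimal penalty" rule).  AIC and BIC variants are provided
for convenience with model dimension ``D_K = 2K - 1`` (``K`` segment
parameters plus ``K - 1`` breakpoints).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CriterionTable",
    "CalibrationError",
    "oracle_penalty_shape",
    "slope_heuristic_beta",
    "select_K",
]


class CalibrationError(RuntimeError):
    """Slope-heuristic calibration failed (no decreasing cost trend)."""


def oracle_penalty_shape(K, n: int):
    """Penalty shape ``K * (1 + 4*sqrt(1.1 + log(n/K)))**2`` (natural log).

    Strictly increasing in ``K`` on ``1..n``.  Accepts scalar or array ``K``.
    """
    K = np.asarray(K, dtype=np.float64)
    if np.any(K < 1) or np.any(K > n):
        raise ValueError("K must lie in [1, n]")
    shape = K * (1.0 + 4.0 * np.sqrt(1.1 + np.log(n / K))) ** 2
    return float(shape) if shape.ndim == 0 else shape


def slope_heuristic_beta(costs, shapes, fit_fraction: float = 0.5) -> float:
    """Calibrate ``beta`` from the large-``K`` cost decrease.

    Fits ``cost ~ a + s * shape`` by least squares on the top
    ``fit_fraction`` of the ``K`` range and returns ``beta = 2 * |s|``.
    Falls back to a median-of-pairwise-slopes (Theil-Sen) fit when the
    least-squares slope is non-negative; raises :class:`CalibrationError`
    if that is non-negative too (costs carry no decreasing trend).
    """
    costs = np.asarray(costs, dtype=np.float64)
    shapes = np.asarray(shapes, dtype=np.float64)
    kmax = len(costs)
    if kmax < 10:
        raise ValueError("slope heuristic needs at least 10 values of K")
    start = int(np.floor(kmax * (1.0 - fit_fraction)))
    x = shapes[start:]
    y = costs[start:]
    slope = np.polyfit(x, y, 1)[0]
    if slope >= 0:
        warnings.warn(
            "least-squares slope non-negative; falling back to median of "
            "pairwise slopes",
            RuntimeWarning,
            stacklevel=2,
        )
        ii, jj = np.triu_indices(len(x), k=1)
        slope = np.median((y[jj] - y[ii]) / (x[jj] - x[ii]))
        if slope >= 0:
            raise CalibrationError(
                "cost does not decrease with the penalty shape at large K; "
                "cannot calibrate beta (series may lack segment structure)"
            )
    return float(2.0 * abs(slope))


@dataclass(frozen=True)
class CriterionTable:
    """Per-``K`` criterion values and the selected number of segments."""

    criterion: str
    K: np.ndarray
    cost: np.ndarray
    penalty: np.ndarray
    beta: float | None
    K_hat: int

    @property
    def values(self) -> np.ndarray:
        return self.cost + self.penalty

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"K": self.K, "cost": self.cost, "penalty": self.penalty,
             "criterion": self.values}
        )


def select_K(result, criterion: str = "oracle", fit_fraction: float = 0.5) -> CriterionTable:
    """Select the number of segments from a fitted :class:`SegmentationResult`.

    ``criterion`` is one of ``"oracle"`` (penalty shape above, ``beta`` by
    the slope heuristic), ``"aic"`` (``cost + D_K``) or ``"bic"``
    (``cost + (D_K / 2) * log n``), with ``D_K = 2K - 1``.

    The cost term is the optimal segmentation cost ``C_{K,n}``; for the
    negative binomial family this coincides with the plug-in criterion
    cost evaluated at ``theta_r = phi / (phi + mean_r)``, which is the
    exact per-segment minimizer.
    """
    costs = np.asarray(result.optimal_costs, dtype=np.float64)
    kmax = len(costs)
    K = np.arange(1, kmax + 1)
    n = result.n
    beta = None
    if criterion == "oracle":
        shapes = oracle_penalty_shape(K, n)
        beta = slope_heuristic_beta(costs, shapes, fit_fraction)
        penalty = beta * shapes
    elif criterion == "aic":
        penalty = (2.0 * K - 1.0).astype(np.float64)
    elif criterion == "bic":
        penalty = (2.0 * K - 1.0) / 2.0 * np.log(n)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    K_hat = int(K[np.argmin(costs + penalty)])
    return CriterionTable(criterion, K, costs, penalty, beta, K_hat)
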