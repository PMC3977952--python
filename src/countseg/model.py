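"""Model / Results interface for count-series segmentation.

:class:`CountSegmentation` is the model object: it holds the observed
series, the loss family and the dispersion policy.  Calling :meth:`fit`
runs plateau compression, dispersion estimation (when needed) and the
pruned DP sweep, returning a :class:`SegmentationResults` that carries the
optimal costs for every number of segments up to ``kmax``, the selected
model, per-segment estimates and a ``summary()`` table.

Example
-------
>>> from countseg import CountSegmentation, simulate_profile
>>> prof = simulate_profile(n=1000, K=10, phi=2.3, seed=7)
>>> res = CountSegmentation(prof.series).fit()
>>> res.k_hat  # number of segments chosen by the oracle penalty
10
"""

from __future__ import annotations

import numpy as np

from .dispersion import DispersionEstimate, estimate_phi
from .losses import LossModel
from .model_selection import CriterionTable, select_K
from .pdp import SegmentationResult, best_segmentation_with_breakpoint, pdp_pass

__all__ = ["CountSegmentation", "SegmentationResults"]


class CountSegmentation:
    """Segmentation model for a one-dimensional count (or real) series.

    Parameters
    ----------
    counts : array-like
        Observed series, one value per genomic position.  Non-negative
        integers for the count families.
    family : {"nbinom", "poisson", "gaussian"}
        Loss family; the default negative binomial is the appropriate
        choice for overdispersed sequencing coverage.
    phi : float, optional
        NB dispersion.  When omitted (nbinom only) it is estimated at fit
        time by the windowed-median moment procedure.
    weights : array-like, optional
        Positive integer weights for pre-aggregated input (e.g. bedGraph
        intervals); disables internal compression.
    compress : bool
        Plateau-compress before sweeping (default True; lossless for the
        optimal costs).
    """

    def __init__(self, counts, family: str = "nbinom", phi: float | None = None,
                 weights=None, compress: bool = True):
        self.endog = np.asarray(counts)
        if self.endog.ndim != 1 or self.endog.size == 0:
            raise ValueError("counts must be a non-empty 1-d array")
        self.family = family
        self.phi = phi
        self.weights = None if weights is None else np.asarray(weights)
        self.compress = compress and weights is None
        if family != "nbinom" and phi is not None:
            raise ValueError("phi only applies to the negative binomial family")

    @classmethod
    def from_dataframe(cls, df, column: str = "count", **kwargs) -> "CountSegmentation":
        """Build from a DataFrame column (positions taken as the row order)."""
        return cls(df[column].to_numpy(), **kwargs)

    def default_kmax(self) -> int:
        """``floor(sqrt(m))`` of the effective (compressed) length, >= 1."""
        if self.compress:
            from .compression import compress as _compress

            m = len(_compress(self.endog))
        else:
            m = len(self.endog)
        return max(1, min(int(np.sqrt(m)), m))

    def fit(self, kmax: int | None = None, engine: str = "numba") -> "SegmentationResults":
        """Estimate ``phi`` if needed, sweep up to ``kmax`` segments.

        ``kmax`` defaults to ``floor(sqrt(m))`` of the effective length.
        """
        phi = self.phi
        phi_estimate: DispersionEstimate | None = None
        if self.family == "nbinom" and phi is None:
            phi_estimate = estimate_phi(self.endog)
            phi = phi_estimate.phi_hat
        loss = LossModel(self.family, phi if phi is not None else 1.0)
        if kmax is None:
            kmax = self.default_kmax()
        seg = pdp_pass(
            self.endog, loss, kmax,
            weights=self.weights, use_compression=self.compress, engine=engine,
        )
        return SegmentationResults(self, seg, phi_estimate)


class SegmentationResults:
    """Fitted segmentations for all ``K <= kmax``, plus model selection.

    Attributes
    ----------
    segmentation : SegmentationResult
        Costs, backpointers and breakpoint accessors for every ``K``.
    phi_estimate : DispersionEstimate or None
        Set when the dispersion was estimated from the data.
    """

    def __init__(self, model: CountSegmentation, segmentation: SegmentationResult,
                 phi_estimate: DispersionEstimate | None = None):
        self.model = model
        self.segmentation = segmentation
        self.phi_estimate = phi_estimate
        self._criteria: dict[str, CriterionTable] = {}

    # -- basics ------------------------------------------------------------

    @property
    def phi(self) -> float:
        return self.segmentation.model.phi

    @property
    def kmax(self) -> int:
        return self.segmentation.kmax

    @property
    def nobs(self) -> int:
        return self.segmentation.n

    @property
    def optimal_costs(self) -> np.ndarray:
        """``C_{K,n}`` for ``K = 1..kmax`` (non-increasing)."""
        return self.segmentation.optimal_costs

    # -- model selection ---------------------------------------------------

    def select(self, criterion: str = "oracle") -> CriterionTable:
        """Criterion table and selected ``K`` (cached per criterion)."""
        if criterion not in self._criteria:
            self._criteria[criterion] = select_K(self.segmentation, criterion)
        return self._criteria[criterion]

    @property
    def k_hat(self) -> int:
        """Number of segments under the oracle penalty."""
        return self.select("oracle").K_hat

    # -- per-K accessors ----------------------------------------------------

    def breakpoints(self, k: int | None = None) -> np.ndarray:
        """1-based inclusive segment ends (original coordinates)."""
        return self.segmentation.breakpoints(self.k_hat if k is None else k)

    def theta_hat(self, k: int | None = None) -> np.ndarray:
        return self.segmentation.theta_hat(self.k_hat if k is None else k)

    def labels(self, k: int | None = None) -> np.ndarray:
        from .evaluation import labels_from_breakpoints

        return labels_from_breakpoints(self.breakpoints(k), self.nobs)

    def segment_table(self, k: int | None = None):
        """DataFrame: segment, start, end (1-based inclusive), n_r, mean, theta_hat."""
        import pandas as pd

        k = self.k_hat if k is None else k
        bounds = self.segmentation.segment_bounds(k)
        return pd.DataFrame(
            {
                "segment": np.arange(1, k + 1),
                "start": bounds[:, 0],
                "end": bounds[:, 1],
                "n_r": bounds[:, 1] - bounds[:, 0] + 1,
                "mean": self.segmentation.segment_means(k),
                "theta_hat": self.segmentation.theta_hat(k),
            }
        )

    def constrained_cost(self, K: int, j: int, t: int) -> float:
        """Cost of the best ``K``-segmentation whose ``j``-th change-point is ``t``."""
        _, cost = best_segmentation_with_breakpoint(
            self.model.endog, self.segmentation.model, K, j, t, weights=self.model.weights
        )
        return cost

    # -- reporting -----------------------------------------------------------

    def summary(self, criterion: str = "oracle") -> str:
        """Plain-text report of the fit and the selected segmentation."""
        tab = self.select(criterion)
        seg = self.segmentation
        lines = [
            "Count series segmentation (pruned dynamic programming)",
            "=" * 58,
            f"family:              {seg.model.family}",
            f"n (positions):       {seg.n}",
            f"effective points:    {seg.m}"
            + (f"  (compression x{seg.pmap.compression_factor:.1f})" if seg.pmap else ""),
            f"phi (dispersion):    {seg.model.phi:.6g}"
            + ("  [estimated]" if self.phi_estimate else "")
            if seg.model.family == "nbinom"
            else f"phi:                 n/a ({seg.model.family} loss)",
            f"Kmax:                {self.kmax}",
            f"criterion:           {criterion}"
            + (f"  (beta = {tab.beta:.4g})" if tab.beta is not None else ""),
            f"selected K:          {tab.K_hat}",
            f"cost C_(K,n):        {tab.cost[tab.K_hat - 1]:.6g}",
            "",
            self.segment_table(tab.K_hat).to_string(index=False),
        ]
        return "\n".join(lines)

    def plot(self, k: int | None = None, ax=None, sqrt_scale: bool = True):
        """Plot the series with fitted segment means and change-points."""
        import matplotlib.pyplot as plt

        k = self.k_hat if k is None else k
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        y = np.asarray(self.model.endog, dtype=float)
        ax.plot(np.sqrt(y) if sqrt_scale else y, color="darkred", lw=0.5,
                label="sqrt(counts)" if sqrt_scale else "counts")
        means = self.segmentation.segment_means(k)
        for (a, b), mu in zip(self.segmentation.segment_bounds(k), means):
            v = np.sqrt(mu) if sqrt_scale else mu
            ax.hlines(v, a - 1, b, color="navy", lw=1.5)
        for br in self.breakpoints(k):
            ax.axvline(br, color="steelblue", lw=0.6, alpha=0.6)
        ax.set_xlabel("position")
        ax.set_ylabel("sqrt(count)" if sqrt_scale else "count")
        ax.legend(loc="upper right", frameon=False)
        return ax
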