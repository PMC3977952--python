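"""Synthetic piecewise-constant negative binomial profiles.

The generator mirrors the performance-study design used throughout the
test-bench: a series of length ``n`` split into ``K`` segments (breakpoints
drawn uniformly among compositions with a minimum segment length), with the
NB success probability alternating between two values — 0.8 on odd-indexed
segments (low signal) and 0.2 on even-indexed ones (high signal, since the
mean ``phi*(1-theta)/theta`` grows as ``theta`` falls) — and a single
dispersion ``phi`` shared by all segments.  Typical dispersions: 0.3 for
highly dispersed coverage, 2.3 for reasonably dispersed data.

Sampling uses the gamma-Poisson mixture, so non-integer ``phi`` is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimulatedProfile", "simulate_breakpoints", "simulate_profile", "nb_mean", "nb_var"]


def nb_mean(theta: float, phi: float) -> float:
    """Mean ``phi * (1 - theta) / theta`` of NB(phi, theta)."""
    return phi * (1.0 - theta) / theta


def nb_var(theta: float, phi: float) -> float:
    """Variance ``phi * (1 - theta) / theta**2`` of NB(phi, theta)."""
    return phi * (1.0 - theta) / theta**2


@dataclass(frozen=True)
class SimulatedProfile:
    """A simulated count series together with its ground truth."""

    series: np.ndarray
    true_breaks: np.ndarray  # 1-based inclusive segment ends (K-1 values)
    true_theta: np.ndarray  # per-segment success probabilities
    phi: float
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.series)

    @property
    def K(self) -> int:
        return len(self.true_theta)

    def true_labels(self) -> np.ndarray:
        from .evaluation import labels_from_breakpoints

        return labels_from_breakpoints(self.true_breaks, self.n)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_breakpoints(n: int, K: int, min_len: int = 5, rng=None) -> np.ndarray:
    """Draw ``K - 1`` breakpoints uniformly among compositions of ``n``
    into ``K`` parts each of length >= ``min_len``."""
    if K < 1 or K * min_len > n:
        raise ValueError(f"cannot fit K={K} segments of length >= {min_len} in n={n}")
    if K == 1:
        return np.zeros(0, dtype=np.int64)
    rng = _as_rng(rng)
    # choose K-1 cut positions among the n - K*min_len free units
    free = n - K * min_len
    cuts = np.sort(rng.choice(free + K - 1, size=K - 1, replace=False))
    gaps = np.diff(np.concatenate(([-1], cuts, [free + K - 1]))) - 1
    lengths = gaps + min_len
    return np.cumsum(lengths[:-1]).astype(np.int64)


def nb_rvs(theta: float, phi: float, size: int, rng) -> np.ndarray:
    """NB(phi, theta) draws via the gamma-Poisson mixture (non-integer phi OK)."""
    lam = rng.gamma(shape=phi, scale=(1.0 - theta) / theta, size=size)
    return rng.poisson(lam)


def simulate_profile(
    n: int,
    K: int,
    phi: float,
    theta_high_signal: float = 0.2,
    theta_low_signal: float = 0.8,
    min_len: int = 5,
    seed=None,
) -> SimulatedProfile:
    """Simulate a piecewise-constant NB profile with alternating signal.

    Segment 1 (and every odd segment) uses ``theta_low_signal`` (default
    0.8, low counts); even segments use ``theta_high_signal`` (default 0.2,
    high counts).  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if not phi > 0:
        raise ValueError("phi must be > 0")
    for th in (theta_high_signal, theta_low_signal):
        if not (0.0 < th < 1.0):
            raise ValueError("theta must lie in (0, 1)")
    rng = _as_rng(seed)
    breaks = simulate_breakpoints(n, K, min_len, rng)
    theta = np.where(np.arange(K) % 2 == 0, theta_low_signal, theta_high_signal)
    edges = np.concatenate(([0], breaks, [n]))
    parts = [
        nb_rvs(theta[i], phi, int(edges[i + 1] - edges[i]), rng) for i in range(K)
    ]
    series = np.concatenate(parts).astype(np.int64)
    return SimulatedProfile(
        series, breaks, theta, phi, seed if isinstance(seed, (int, np.integer)) else None
    )
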