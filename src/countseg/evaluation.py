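"""Segmentation-quality metrics.

Two complementary views:

* against a known truth — a Rand index over pairs of positions, measuring
  whether two positions that truly share a segment are estimated to share
  one (and conversely);
* between two segmentations of the same observed profile — the per-position
  Hellinger distance between the negative binomial distributions fitted on
  each side's segment, averaged over positions.

The Rand index here sums over position pairs ``(s, t)`` with ``t >= s + 2``
(adjacent pairs excluded), normalized by ``(n-1)(n-2)``; identical
segmentations score exactly 1 under this pair set.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "labels_from_breakpoints",
    "rand_index",
    "hellinger_nb",
    "hellinger_profile",
]


def labels_from_breakpoints(breaks, n: int) -> np.ndarray:
    """Per-position segment labels (1-based) from 1-based inclusive ends."""
    br = np.asarray(breaks, dtype=np.int64)
    if br.size:
        if np.any(np.diff(br) <= 0) or br[0] < 1 or br[-1] > n - 1:
            raise ValueError("breakpoints must be strictly increasing within [1, n-1]")
    labels = np.ones(n, dtype=np.int64)
    for b in br:
        labels[b:] += 1
    return labels


def _run_lengths(labels: np.ndarray) -> np.ndarray:
    change = np.flatnonzero(np.diff(labels) != 0)
    return np.diff(np.concatenate(([0], change + 1, [len(labels)])))


def _nonadjacent_same_pairs(lengths: np.ndarray) -> int:
    # pairs (s, t), t >= s+2, inside runs of the given lengths
    return int(np.sum((lengths - 1) * (lengths - 2) // 2))


def rand_index(true_labels, est_labels) -> float:
    """Segmentation Rand index over non-adjacent position pairs.

    ``I = 2 * (pairs agreeing on "same segment" + pairs agreeing on
    "different segments") / ((n-1)(n-2))`` where the pair set is all
    ``(s, t)`` with ``t >= s + 2``.  Computed in O(n) from run lengths of
    the two labelings and of their refinement (equivalent to the explicit
    pair sum, which is what the tests enumerate).
    """
    a = np.asarray(true_labels)
    b = np.asarray(est_labels)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError("Rand index needs n >= 3")
    total = (n - 1) * (n - 2) // 2
    same_a = _nonadjacent_same_pairs(_run_lengths(a))
    same_b = _nonadjacent_same_pairs(_run_lengths(b))
    # refinement: positions in the same run of both labelings simultaneously
    joint = a.astype(np.int64) * (b.max() + 1) + b
    same_ab = _nonadjacent_same_pairs(_run_lengths(joint))
    agree = same_ab + (total - same_a - same_b + same_ab)
    return 2.0 * agree / ((n - 1) * (n - 2))


def hellinger_nb(theta1: float, theta2: float, phi: float) -> float:
    """Hellinger distance between NB(phi, theta1) and NB(phi, theta2).

    With pmf ``P(y) = C(y+phi-1, y) theta^phi (1-theta)^y`` the
    Bhattacharyya coefficient has the closed form

        BC = [ sqrt(theta1*theta2) / (1 - sqrt((1-theta1)(1-theta2))) ]**phi

    (sum the generating series of ``C(y+phi-1, y) x^y``), and
    ``H = sqrt(1 - BC)``; ``H`` is in [0, 1] and 0 iff theta1 == theta2.
    """
    for th in (theta1, theta2):
        if not (0.0 < th < 1.0):
            raise ValueError("theta must lie in (0, 1)")
    if not phi > 0:
        raise ValueError("phi must be > 0")
    bc = (
        math.sqrt(theta1 * theta2)
        / (1.0 - math.sqrt((1.0 - theta1) * (1.0 - theta2)))
    ) ** phi
    return math.sqrt(max(0.0, 1.0 - bc))


def _fitted_theta_per_position(breaks, series, phi) -> np.ndarray:
    y = np.asarray(series, dtype=np.float64)
    n = len(y)
    labels = labels_from_breakpoints(breaks, n)
    theta_pos = np.empty(n)
    for lab in np.unique(labels):
        mask = labels == lab
        mean = y[mask].mean()
        # clip into the open interval: an all-zero segment fits theta -> 1
        theta_pos[mask] = min(phi / (phi + mean), 1.0 - 1e-12)
    return theta_pos


def hellinger_profile(breaks_a, breaks_b, series, phi: float) -> tuple[np.ndarray, float]:
    """Per-position Hellinger distances between two segmentations, and their mean.

    Each side's segments get the plug-in fit ``theta_r = phi / (phi + mean_r)``;
    position ``t`` contributes the distance between the two fitted
    distributions covering it.  Returns ``(H_t array, sum_t H_t / n)``.
    """
    y = np.asarray(series, dtype=np.float64)
    ta = _fitted_theta_per_position(breaks_a, y, phi)
    tb = _fitted_theta_per_position(breaks_b, y, phi)
    h = np.array([hellinger_nb(x1, x2, phi) if x1 != x2 else 0.0 for x1, x2 in zip(ta, tb)])
    return h, float(h.mean())
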