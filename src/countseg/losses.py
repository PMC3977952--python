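"""One-parameter convex loss families for segment cost functions.

Each family defines a point loss ``gamma(y, theta)`` that is convex in the
segment parameter ``theta``, together with a compact accumulator holding the
cost of a segment as a function of ``theta``.  These are the three ingredients
the pruned dynamic programming sweep needs from a loss:

(a) point additivity  -- a segment's cost is the sum of its point losses,
(b) convexity in ``theta``,
(c) constant-size storage and O(1) update when a point is appended.

Families
--------
``nbinom``
    Negative binomial in the exponential-family (success probability)
    parametrization: ``gamma(y, theta) = -phi*log(theta) - y*log(1-theta)``
    with ``theta`` in (0, 1) and a global dispersion ``phi > 0`` shared by
    all segments.  Mean ``phi*(1-theta)/theta``, variance
    ``phi*(1-theta)/theta**2``; small ``theta`` means high signal.
``poisson``
    ``gamma(y, theta) = theta - y*log(theta)`` with ``theta`` in (0, inf)
    (the segment intensity).
``gaussian``
    ``gamma(y, theta) = (y - theta)**2`` (homoscedastic mean shift).

Losses are defined up to an additive term that does not depend on ``theta``
(it cancels in every cost comparison); the full pmf, including that term,
lives in :mod:`countseg.evaluation` and :mod:`countseg.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "LossModel",
    "SegmentCostAccumulator",
    "point_loss",
    "accumulate",
    "cost_min",
    "level_set",
    "EPS",
    "TOL_THETA",
]

#: Clipping distance from the open parameter-space boundaries.  Keeps
#: log terms finite for degenerate segments (e.g. all-zero counts under the
#: negative binomial) without measurably perturbing costs.
EPS = 1e-12

#: Absolute tolerance in ``theta`` for the level-set root finder.
TOL_THETA = 1e-9

_MAX_BISECT = 200

#: Sentinel standing in for an unbounded parameter-space edge.
_BIG = 1e300

_FAMILIES = ("nbinom", "poisson", "gaussian")


@dataclass(frozen=True)
class LossModel:
    """A loss family plus its fixed nuisance parameter.

    Parameters
    ----------
    family : {"nbinom", "poisson", "gaussian"}
        Loss family.
    phi : float
        Negative binomial dispersion (shape) parameter, shared by all
        segments.  Ignored by the Poisson and Gaussian families.
    """

    family: str
    phi: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown loss family {self.family!r}; expected one of {_FAMILIES}"
            )
        if self.family == "nbinom" and not (self.phi > 0):
            raise ValueError("negative binomial dispersion phi must be > 0")

    @property
    def param_space(self) -> tuple[float, float]:
        """Open interval of admissible ``theta`` values."""
        if self.family == "nbinom":
            return (0.0, 1.0)
        if self.family == "poisson":
            return (0.0, math.inf)
        return (-math.inf, math.inf)

    @property
    def clipped_space(self) -> tuple[float, float]:
        """Parameter space with the EPS clip applied (closed, computable)."""
        if self.family == "nbinom":
            return (EPS, 1.0 - EPS)
        if self.family == "poisson":
            return (EPS, _BIG)
        return (-_BIG, _BIG)

    def _check_theta(self, theta: float) -> None:
        lo, hi = self.param_space
        if not (lo < theta < hi):
            raise ValueError(
                f"theta={theta} outside the open parameter space ({lo}, {hi}) "
                f"of the {self.family} loss"
            )


def point_loss(y: float, theta: float, model: LossModel) -> float:
    """Loss of a single observation ``y`` under segment parameter ``theta``.

    Convex in ``theta`` for fixed ``y``; additive constants independent of
    ``theta`` are dropped.
    """
    model._check_theta(theta)
    if y < 0:
        raise ValueError("counts must be non-negative")
    if model.family == "nbinom":
        return -model.phi * math.log(theta) - y * math.log1p(-theta)
    if model.family == "poisson":
        return theta - y * math.log(theta)
    return (y - theta) ** 2


@dataclass
class SegmentCostAccumulator:
    """Constant-size representation of a segment's cost function.

    For the count families the cost of a segment built from weighted points
    ``(y_i, w_i)`` is

    * nbinom:  ``-d1*log(theta) - d2*log(1-theta)`` with
      ``d1 = phi * sum(w)`` and ``d2 = sum(w*y)``;
    * poisson: ``d1*theta - d2*log(theta)`` with ``d1 = sum(w)`` and
      ``d2 = sum(w*y)``;

    and for the Gaussian the quadratic ``s0*theta**2 - 2*s1*theta + s2``
    where ``s0 = sum(w)``, ``s1 = sum(w*y)``, ``s2 = sum(w*y**2)``.

    An optional ``offset`` is added to every evaluation; it hosts the
    constant ``C_{k-1,tau}`` during the DP sweep and leaves room for a
    future per-segment parameter penalty ``g(theta)`` initialization.
    """

    model: LossModel
    offset: float = 0.0
    s0: float = field(default=0.0)  # sum of weights
    s1: float = field(default=0.0)  # sum of w*y
    s2: float = field(default=0.0)  # sum of w*y^2 (gaussian only)
    npoints: int = field(default=0)

    # -- bookkeeping -------------------------------------------------------

    @property
    def d1(self) -> float:
        """Coefficient of ``-log(theta)`` (nbinom) or ``theta`` (poisson)."""
        if self.model.family == "nbinom":
            return self.model.phi * self.s0
        return self.s0

    @property
    def d2(self) -> float:
        """Coefficient of ``-log(1-theta)`` (nbinom) / ``-log(theta)`` (poisson)."""
        return self.s1

    def add(self, y: float, w: float = 1.0) -> "SegmentCostAccumulator":
        """Fold ``w`` copies of observation ``y`` into the segment (in place)."""
        if w <= 0:
            raise ValueError("weight must be positive")
        if self.model.family != "gaussian" and y < 0:
            raise ValueError("counts must be non-negative")
        self.s0 += w
        self.s1 += w * y
        self.s2 += w * y * y
        self.npoints += 1
        return self

    def copy(self) -> "SegmentCostAccumulator":
        return SegmentCostAccumulator(
            self.model, self.offset, self.s0, self.s1, self.s2, self.npoints
        )

    # -- evaluation --------------------------------------------------------

    def cost(self, theta: float) -> float:
        """Segment cost at ``theta`` (offset included)."""
        self.model._check_theta(theta)
        fam = self.model.family
        if fam == "nbinom":
            return self.offset - self.d1 * math.log(theta) - self.d2 * math.log1p(-theta)
        if fam == "poisson":
            return self.offset + self.d1 * theta - self.d2 * math.log(theta)
        return self.offset + self.s0 * theta * theta - 2.0 * self.s1 * theta + self.s2

    def argmin(self) -> float:
        """Unconstrained minimizer, clipped into the computable space."""
        if self.s0 <= 0:
            raise ValueError("cost_min of an empty accumulator")
        fam = self.model.family
        lo, hi = self.model.clipped_space
        if fam == "nbinom":
            d1, d2 = self.d1, self.d2
            th = d1 / (d1 + d2) if d2 > 0 else hi
        elif fam == "poisson":
            th = self.s1 / self.s0
        else:
            th = self.s1 / self.s0
        return min(max(th, lo), hi)

    def min_value(self) -> float:
        return self.cost(self.argmin())


def accumulate(
    acc: SegmentCostAccumulator, y: float, w: float, model: LossModel
) -> SegmentCostAccumulator:
    """Return a new accumulator equal to ``acc`` plus ``w * gamma(y, .)``."""
    if model != acc.model:
        raise ValueError("accumulator was built for a different loss model")
    return acc.copy().add(y, w)


def cost_min(acc: SegmentCostAccumulator) -> tuple[float, float]:
    """Minimizer and minimal cost of a segment, ``min_theta c(r, theta)``.

    Closed forms: nbinom ``theta = d1/(d1+d2)``, poisson ``theta = mean``,
    gaussian ``theta = weighted mean``; the minimizer is clipped into the
    EPS-closed parameter space.
    """
    th = acc.argmin()
    return th, acc.cost(th)


def _bisect(f, lo: float, hi: float, tol: float = TOL_THETA) -> float:
    """Root of increasing-sign ``f`` on [lo, hi] with f(lo) <= 0 <= f(hi)."""
    for _ in range(_MAX_BISECT):
        mid = 0.5 * (lo + hi)
        if hi - lo <= tol:
            return mid
        if f(mid) <= 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def level_set(
    acc: SegmentCostAccumulator, offset: float, c: float
) -> tuple[float, float] | None:
    """Solve ``offset + cost(theta) <= c`` for ``theta``.

    The cost is convex, so the solution set is a single closed interval
    (possibly empty -> ``None``, possibly degenerate).  The Gaussian case is
    solved in closed form via the quadratic roots; the count families by
    bracketed bisection on each side of the minimizer.
    """
    fam = acc.model.family
    lo_b, hi_b = acc.model.clipped_space

    if fam == "gaussian":
        # s0*th^2 - 2*s1*th + (s2 + acc.offset + offset - c) <= 0
        a, b = acc.s0, -2.0 * acc.s1
        c0 = acc.s2 + acc.offset + offset - c
        if a <= 0:  # empty accumulator: constant function
            return (lo_b, hi_b) if c0 <= 0 else None
        disc = b * b - 4.0 * a * c0
        if disc < 0:
            return None
        root = math.sqrt(disc)
        return ((-b - root) / (2.0 * a), (-b + root) / (2.0 * a))

    if acc.s0 <= 0:  # constant function (no points yet)
        return (lo_b, hi_b) if acc.offset + offset <= c else None

    th = acc.argmin()
    fmin = offset + acc.cost(th)
    if fmin > c:
        return None

    def g(x: float) -> float:
        return offset + acc.cost(x) - c

    # left endpoint
    if g(lo_b) <= 0.0:
        left = lo_b
    else:
        # g decreasing on [lo_b, th]: find where it crosses 0
        left = _bisect(lambda x: -g(x), lo_b, th)

    # right endpoint
    if fam == "nbinom":
        if g(hi_b) <= 0.0:
            right = hi_b
        else:
            right = _bisect(g, th, hi_b)
    else:  # poisson: expand a bracket geometrically above the minimizer
        hi = max(2.0 * th, th + 1.0)
        while g(hi) <= 0.0 and hi < _BIG:
            hi *= 2.0
        right = hi if hi >= _BIG else _bisect(g, th, hi)

    return (left, right)
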