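"""Loss families: point losses, accumulators, closed-form minimizers, level sets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from countseg.losses import (
    EPS,
    LossModel,
    SegmentCostAccumulator,
    accumulate,
    cost_min,
    level_set,
    point_loss,
)

NB1 = LossModel("nbinom", 1.0)
NB3 = LossModel("nbinom", 3.0)
POIS = LossModel("poisson")
GAUSS = LossModel("gaussian")


@pytest.mark.parametrize(
    "y,theta,model,expected",
    [
        (0, 0.5, NB1, math.log(2.0)),
        (3, 3.0, GAUSS, 0.0),
        (2, 1.0 / 3.0, NB1, -math.log(1 / 3) - 2 * math.log(2 / 3)),
        (5, 5.0, POIS, 5.0 - 5.0 * math.log(5.0)),
    ],
)
def test_point_loss_values(y, theta, model, expected):
    assert point_loss(y, theta, model) == pytest.approx(expected, abs=1e-12)


def test_point_loss_nb_minimizer_is_phi_over_phi_plus_y():
    # dense grid search over theta confirms the closed-form minimizer
    grid = np.linspace(1e-6, 1 - 1e-6, 20001)
    vals = [point_loss(2, th, NB1) for th in grid]
    th_grid = grid[int(np.argmin(vals))]
    assert th_grid == pytest.approx(1.0 / 3.0, abs=1e-3)
    assert min(vals) == pytest.approx(1.909543, abs=1e-4)


def test_point_loss_domain_errors():
    with pytest.raises(ValueError):
        point_loss(1, 1.5, NB1)
    with pytest.raises(ValueError):
        point_loss(1, -0.1, POIS)
    with pytest.raises(ValueError):
        point_loss(-1, 0.5, NB1)


def test_accumulate_nbinom_update_rule():
    acc = SegmentCostAccumulator(NB3).add(4, 1)
    assert acc.d1 == pytest.approx(3.0)
    assert acc.d2 == pytest.approx(4.0)


def test_accumulate_weight_equals_repetition():
    a = SegmentCostAccumulator(NB3).add(4, 3)
    b = SegmentCostAccumulator(NB3)
    for _ in range(3):
        b.add(4, 1)
    for th in (0.1, 0.5, 0.9):
        assert a.cost(th) == pytest.approx(b.cost(th), rel=1e-12)


def test_accumulate_poisson_example():
    acc = SegmentCostAccumulator(POIS)
    for y in (2, 0, 5):
        acc.add(y)
    assert (acc.d1, acc.d2) == (3.0, 7.0)
    assert acc.cost(1.0) == pytest.approx(3.0)


def test_accumulate_functional_form_copies():
    acc = SegmentCostAccumulator(POIS).add(1)
    acc2 = accumulate(acc, 5, 1, POIS)
    assert acc.s0 == 1 and acc2.s0 == 2


@pytest.mark.parametrize(
    "model,points,theta_exp,cost_exp",
    [
        (NB3, [2, 4, 6], 9 / 21, -9 * math.log(3 / 7) - 12 * math.log(4 / 7)),
        (POIS, [5, 5, 5], 5.0, 15 - 15 * math.log(5)),
        (GAUSS, [1, 2, 3], 2.0, 2.0),
    ],
)
def test_cost_min_closed_forms(model, points, theta_exp, cost_exp):
    acc = SegmentCostAccumulator(model)
    for y in points:
        acc.add(y)
    th, c = cost_min(acc)
    assert th == pytest.approx(theta_exp, abs=1e-10)
    assert c == pytest.approx(cost_exp, rel=1e-9)


def test_cost_min_all_zero_nbinom_clips_to_boundary():
    acc = SegmentCostAccumulator(NB1)
    for _ in range(4):
        acc.add(0)
    th, c = cost_min(acc)
    assert th == pytest.approx(1.0 - EPS)
    assert abs(c) < 1e-9


def test_cost_min_empty_accumulator_errors():
    with pytest.raises(ValueError):
        cost_min(SegmentCostAccumulator(POIS))


@pytest.mark.parametrize("seed", range(10))
def test_cost_min_matches_grid_search(loss_model, seed):
    rng = np.random.default_rng(seed)
    acc = SegmentCostAccumulator(loss_model)
    for y in rng.poisson(3.0, 8):
        acc.add(float(y), float(rng.integers(1, 4)))
    th, c = cost_min(acc)
    if loss_model.family == "gaussian":
        grid = np.linspace(th - 3, th + 3, 4001)
    elif loss_model.family == "poisson":
        grid = np.linspace(1e-4, max(2 * th, 5.0), 4001)
    else:
        grid = np.linspace(1e-4, 1 - 1e-4, 4001)
    vals = np.array([acc.cost(g) for g in grid])
    assert c <= vals.min() + 1e-6


def test_level_set_below_minimum_empty(loss_model):
    acc = SegmentCostAccumulator(loss_model)
    acc.add(2).add(3)
    _, cmin = cost_min(acc)
    assert level_set(acc, 0.0, cmin - 1.0) is None


def test_level_set_tangent_is_degenerate(loss_model):
    acc = SegmentCostAccumulator(loss_model)
    acc.add(2).add(5)
    th, cmin = cost_min(acc)
    lo, hi = level_set(acc, 0.0, cmin + 1e-14)
    assert lo == pytest.approx(th, abs=1e-4)
    assert hi == pytest.approx(th, abs=1e-4)


def test_level_set_gaussian_closed_form():
    acc = SegmentCostAccumulator(GAUSS)
    acc.add(0).add(2)  # 2(theta-1)^2 + 2
    lo, hi = level_set(acc, 0.0, 4.0)
    assert (lo, hi) == pytest.approx((0.0, 2.0), abs=1e-12)


@pytest.mark.parametrize("seed", range(8))
def test_level_set_endpoints_and_interior(loss_model, seed):
    rng = np.random.default_rng(100 + seed)
    acc = SegmentCostAccumulator(loss_model)
    for y in rng.poisson(2.0, 6):
        acc.add(float(y))
    th, cmin = cost_min(acc)
    c = cmin + float(rng.uniform(0.5, 5.0))
    lo, hi = level_set(acc, 0.0, c)
    dlo, dhi = loss_model.clipped_space
    for end in (lo, hi):
        if end in (dlo, dhi):  # clipped at the domain boundary
            assert acc.cost(end) <= c + 1e-6
        else:
            assert acc.cost(end) == pytest.approx(c, abs=1e-5)
    for th_in in np.linspace(lo, hi, 17):
        assert acc.cost(th_in) <= c + 1e-6


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.lists(st.integers(0, 30), min_size=1, max_size=12),
    t1=st.floats(0.05, 0.95),
    t2=st.floats(0.05, 0.95),
)
def test_convexity_and_point_additivity_nbinom(data, t1, t2):
    """Midpoint convexity and additivity of the accumulated segment cost."""
    model = LossModel("nbinom", 0.7)
    acc = SegmentCostAccumulator(model)
    for y in data:
        acc.add(y)
    mid = 0.5 * (t1 + t2)
    assert acc.cost(mid) <= 0.5 * (acc.cost(t1) + acc.cost(t2)) + 1e-9
    direct = sum(point_loss(y, t1, model) for y in data)
    assert acc.cost(t1) == pytest.approx(direct, rel=1e-10, abs=1e-10)
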