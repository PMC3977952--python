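"""Pruned DP sweep: exactness vs the unpruned oracle, tracebacks, pruning."""

import itertools
import math

import numpy as np
import pytest

from conftest import random_series
from countseg.losses import LossModel, SegmentCostAccumulator
from countseg.pdp import (
    backtrack,
    best_segmentation_with_breakpoint,
    naive_dp,
    pdp_pass,
)

POIS = LossModel("poisson")


def segment_cost_from_breaks(y, breaks, model, weights=None):
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    edges = np.concatenate(([0], np.asarray(breaks, dtype=int), [len(y)]))
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        acc = SegmentCostAccumulator(model)
        for t in range(a, b):
            acc.add(y[t], w[t])
        total += acc.min_value()
    return total


def test_constant_series_costs_flat_in_k():
    res = pdp_pass(np.full(30, 4.0), POIS, 5, use_compression=False)
    assert np.allclose(res.optimal_costs, res.optimal_costs[0], rtol=1e-9)


def test_step_series_poisson_exhaustive():
    y = np.array([0, 0, 0, 5, 5, 5], dtype=float)
    res = pdp_pass(y, POIS, 2, use_compression=False)
    assert list(res.breakpoints(2)) == [3]
    assert res.costs[2, 6] == pytest.approx(15 - 15 * math.log(5), abs=1e-8)
    th = res.theta_hat(2)
    assert th[0] == pytest.approx(0.0, abs=1e-9)
    assert th[1] == pytest.approx(5.0)
    # against brute force over the 5 possible breakpoints
    brute = min(segment_cost_from_breaks(y, [t], POIS) for t in range(1, 6))
    assert res.costs[2, 6] == pytest.approx(brute, rel=1e-10)


@pytest.mark.parametrize("engine", ["numba", "python"])
@pytest.mark.parametrize("seed", range(6))
def test_pdp_matches_naive_dp(family, loss_model, seed, engine):
    y = random_series(family, 60, seed)
    kmax = 6
    oracle = naive_dp(y, loss_model, kmax)
    res = pdp_pass(y, loss_model, kmax, use_compression=False, engine=engine)
    num = res.costs[1:, len(y)]
    ref = oracle[1:, len(y)]
    assert np.all(np.abs(num - ref) <= 1e-8 * np.maximum(1.0, np.abs(ref)))


@pytest.mark.parametrize("seed", range(4))
def test_traceback_cost_consistency(family, loss_model, seed):
    y = random_series(family, 80, 50 + seed)
    res = pdp_pass(y, loss_model, 6, use_compression=False)
    for k in range(1, 7):
        br = res.breakpoints(k, original=False)
        assert len(br) == k - 1
        assert np.all(np.diff(br) > 0)
        recomputed = segment_cost_from_breaks(y, br, loss_model)
        assert recomputed == pytest.approx(res.costs[k, len(y)], rel=1e-8, abs=1e-8)


def test_monotonicity_in_k(family, loss_model):
    y = random_series(family, 120, 3)
    res = pdp_pass(y, loss_model, 10, use_compression=False)
    c = res.optimal_costs
    assert np.all(c[1:] <= c[:-1] + 1e-9 * np.maximum(1.0, np.abs(c[:-1])))


def test_backtrack_k1_empty_and_bounds():
    y = random_series("poisson", 40, 0)
    res = pdp_pass(y, POIS, 4, use_compression=False)
    assert len(backtrack(res, 1)) == 0
    with pytest.raises(ValueError):
        backtrack(res, 5)


def test_tie_break_determinism():
    y = random_series("nbinom", 100, 11)
    model = LossModel("nbinom", 0.5)
    b1 = pdp_pass(y, model, 6).breakpoints(5)
    b2 = pdp_pass(y, model, 6).breakpoints(5)
    assert np.array_equal(b1, b2)


def test_kmax_validation():
    with pytest.raises(ValueError):
        pdp_pass([1, 2, 3], POIS, 4, use_compression=False)
    with pytest.raises(ValueError):
        pdp_pass([1.5, 2.2], POIS, 1)  # non-integer counts


def test_naive_dp_partition_cardinality():
    """Exhaustive enumeration: C(t-1, k-1) partitions; min matches naive_dp."""
    y = random_series("poisson", 5, 2)
    k = 3
    parts = list(itertools.combinations(range(1, 5), k - 1))
    assert len(parts) == math.comb(4, 2) == 6
    best = min(segment_cost_from_breaks(y, p, POIS) for p in parts)
    C = naive_dp(y, POIS, k)
    assert C[k, 5] == pytest.approx(best, rel=1e-10)


def test_naive_dp_k_equals_n_single_point_segments():
    y = random_series("nbinom", 8, 4)
    model = LossModel("nbinom", 0.5)
    C = naive_dp(y, model, 8)
    expect = sum(
        SegmentCostAccumulator(model).add(float(v)).min_value() for v in y
    )
    assert C[8, 8] == pytest.approx(expect, rel=1e-10)


def test_live_sets_cover_parameter_space():
    """Instrumented sweep: candidate live sets jointly cover I_s at every step."""
    y = random_series("poisson", 50, 9)
    res = pdp_pass(y, POIS, 4, use_compression=False, engine="python",
                   record_live_sets=True)
    dlo, dhi = POIS.clipped_space
    assert res.live_trace
    for _k, _t, sets in res.live_trace:
        ivals = sorted(live for _tau, live in sets)
        cover = dlo
        for lo, hi in ivals:
            assert lo <= cover + 1e-6  # no gap before this interval
            cover = max(cover, hi)
        assert cover >= dhi - 1e-6


def test_pruned_candidates_never_reappear():
    """Once pruned, a tau is absent from all later live-set snapshots (same k)."""
    y = random_series("nbinom", 60, 13)
    model = LossModel("nbinom", 0.5)
    res = pdp_pass(y, model, 4, use_compression=False, engine="python",
                   record_live_sets=True)
    seen: dict[int, set] = {}
    pruned: dict[int, set] = {}
    for k, _t, sets in res.live_trace:
        now = {tau for tau, _ in sets}
        prev = seen.get(k, set())
        gone = prev - now
        pruned.setdefault(k, set()).update(gone)
        assert not (now & pruned[k]), "pruned candidate re-entered the list"
        seen[k] = now | prev


@pytest.mark.parametrize("j", [1, 2])
def test_best_segmentation_with_breakpoint_decomposition(j):
    y = random_series("poisson", 40, 7)
    K = 3
    res = pdp_pass(y, POIS, K, use_compression=False)
    n = len(y)
    costs = [
        best_segmentation_with_breakpoint(y, POIS, K, j, t)[1]
        for t in range(j, n - (K - j) + 1)
    ]
    assert min(costs) == pytest.approx(res.costs[K, n], rel=1e-8)


def test_best_segmentation_step_series():
    y = np.array([0, 0, 0, 5, 5, 5], dtype=float)
    uncon = pdp_pass(y, POIS, 2, use_compression=False).costs[2, 6]
    costs = {t: best_segmentation_with_breakpoint(y, POIS, 2, 1, t)[1] for t in range(1, 6)}
    assert costs[3] == pytest.approx(uncon, rel=1e-10)
    assert min(costs, key=costs.get) == 3
    br, c3 = best_segmentation_with_breakpoint(y, POIS, 2, 1, 3)
    assert list(br) == [3]
    with pytest.raises(ValueError):
        best_segmentation_with_breakpoint(y, POIS, 2, 1, 6)
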