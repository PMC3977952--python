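"""Compiled inner loop of the pruned dynamic programming sweep.

Mirrors the reference implementation in :mod:`countseg.pdp` (same loss
closed forms as :mod:`countseg.losses`); the two are pinned together by the
oracle-equivalence test suite.  Families are coded 0 = nbinom, 1 = poisson,
2 = gaussian.  Candidate live sets are single intervals; the entering
candidate receives the interval hull of the uncovered parameter region,
which can only make pruning conservative, never the costs wrong.
"""

import numpy as np
from numba import njit

EPS = 1e-12
BIG = 1e300
TOL = 1e-9
_GAP_TOL = 4e-9
_REL_TIE = 1e-10
_MAX_BISECT = 200


@njit(cache=True)
def _cost_at(theta, s0, s1, s2, phi, family):
    if family == 0:
        return -phi * s0 * np.log(theta) - s1 * np.log1p(-theta)
    elif family == 1:
        return s0 * theta - s1 * np.log(theta)
    return s0 * theta * theta - 2.0 * s1 * theta + s2


@njit(cache=True)
def _argmin_theta(s0, s1, phi, family):
    if family == 0:
        if s1 <= 0.0:
            return 1.0 - EPS
        d1 = phi * s0
        th = d1 / (d1 + s1)
        if th < EPS:
            th = EPS
        elif th > 1.0 - EPS:
            th = 1.0 - EPS
        return th
    th = s1 / s0
    if family == 1 and th < EPS:
        th = EPS
    return th


@njit(cache=True)
def _level_set(s0, s1, s2, phi, family, offset, c):
    """Interval {theta : offset + cost(theta) <= c}; empty encoded lo > hi."""
    if family == 2:
        a = s0
        c0 = s2 + offset - c
        if a <= 0.0:
            if c0 <= 0.0:
                return -BIG, BIG
            return 1.0, 0.0
        disc = s1 * s1 - a * c0
        if disc < 0.0:
            return 1.0, 0.0
        r = np.sqrt(disc)
        return (s1 - r) / a, (s1 + r) / a

    if family == 0:
        dlo, dhi = EPS, 1.0 - EPS
    else:
        dlo, dhi = EPS, BIG
    if s0 <= 0.0:
        if offset <= c:
            return dlo, dhi
        return 1.0, 0.0
    th = _argmin_theta(s0, s1, phi, family)
    if offset + _cost_at(th, s0, s1, s2, phi, family) > c:
        return 1.0, 0.0

    # left endpoint: cost decreasing on [dlo, th]
    if offset + _cost_at(dlo, s0, s1, s2, phi, family) <= c:
        left = dlo
    else:
        lo = dlo
        hi = th
        for _ in range(_MAX_BISECT):
            mid = 0.5 * (lo + hi)
            if hi - lo <= TOL:
                break
            if offset + _cost_at(mid, s0, s1, s2, phi, family) > c:
                lo = mid
            else:
                hi = mid
        left = 0.5 * (lo + hi)

    # right endpoint: cost increasing on [th, dhi]
    if family == 0:
        if offset + _cost_at(dhi, s0, s1, s2, phi, family) <= c:
            return left, dhi
        lo = th
        hi = dhi
    else:
        hi = 2.0 * th if 2.0 * th > th + 1.0 else th + 1.0
        while hi < BIG and offset + _cost_at(hi, s0, s1, s2, phi, family) <= c:
            hi *= 2.0
        if hi >= BIG:
            return left, BIG
        lo = th
    for _ in range(_MAX_BISECT):
        mid = 0.5 * (lo + hi)
        if hi - lo <= TOL:
            break
        if offset + _cost_at(mid, s0, s1, s2, phi, family) <= c:
            lo = mid
        else:
            hi = mid
    return left, 0.5 * (lo + hi)


@njit(cache=True)
def pdp_sweep(y, w, phi, family, kmax):
    """Optimal costs C[k, t] and backpointers for k = 1..kmax, t = 1..m.

    y, w : float64 arrays of (possibly plateau-compressed) values / weights.
    Returns (C, BP) with C of shape (kmax+1, m+1); BP[k, t] is the 1-based
    inclusive end of segment k-1 in the optimal k-segmentation of points
    1..t (smallest such end under near-ties).
    """
    m = y.shape[0]
    C = np.full((kmax + 1, m + 1), np.inf)
    BP = np.zeros((kmax + 1, m + 1), np.int64)
    C[0, 0] = 0.0

    s0 = 0.0
    s1 = 0.0
    s2 = 0.0
    for t in range(1, m + 1):
        wv = w[t - 1]
        yv = y[t - 1]
        s0 += wv
        s1 += wv * yv
        s2 += wv * yv * yv
        th = _argmin_theta(s0, s1, phi, family)
        C[1, t] = _cost_at(th, s0, s1, s2, phi, family)

    if family == 0:
        dlo, dhi = EPS, 1.0 - EPS
    elif family == 1:
        dlo, dhi = EPS, BIG
    else:
        dlo, dhi = -BIG, BIG

    tau = np.empty(m + 2, np.int64)
    cst = np.empty(m + 2)
    a0 = np.empty(m + 2)
    a1 = np.empty(m + 2)
    a2 = np.empty(m + 2)
    slo = np.empty(m + 2)
    shi = np.empty(m + 2)
    vals = np.empty(m + 2)
    order = np.empty(m + 2, np.int64)

    for k in range(2, kmax + 1):
        nc = 1
        tau[0] = k - 1
        cst[0] = C[k - 1, k - 1]
        a0[0] = 0.0
        a1[0] = 0.0
        a2[0] = 0.0
        slo[0] = dlo
        shi[0] = dhi
        for t in range(k, m + 1):
            yv = y[t - 1]
            wv = w[t - 1]
            best = np.inf
            for i in range(nc):
                a0[i] += wv
                a1[i] += wv * yv
                a2[i] += wv * yv * yv
                th = _argmin_theta(a0[i], a1[i], phi, family)
                if th < slo[i]:
                    th = slo[i]
                elif th > shi[i]:
                    th = shi[i]
                v = cst[i] + _cost_at(th, a0[i], a1[i], a2[i], phi, family)
                vals[i] = v
                if v < best:
                    best = v
            # smallest tau among near-ties (candidates stored in tau order)
            tie = best + _REL_TIE * (abs(best) if abs(best) > 1.0 else 1.0)
            arg = 0
            for i in range(nc):
                if vals[i] <= tie:
                    arg = i
                    break
            C[k, t] = best
            BP[k, t] = tau[arg]

            if t == m:
                break

            # prune against the entering candidate's constant C[k-1, t]
            thr = C[k - 1, t]
            j = 0
            for i in range(nc):
                lo_, hi_ = _level_set(a0[i], a1[i], a2[i], phi, family, cst[i], thr)
                nlo = slo[i] if slo[i] > lo_ else lo_
                nhi = shi[i] if shi[i] < hi_ else hi_
                if nlo <= nhi:
                    tau[j] = tau[i]
                    cst[j] = cst[i]
                    a0[j] = a0[i]
                    a1[j] = a1[i]
                    a2[j] = a2[i]
                    slo[j] = nlo
                    shi[j] = nhi
                    j += 1
            nc = j

            # entering candidate tau = t owns the uncovered region (hull)
            if nc == 0:
                has_gap = True
                new_lo = dlo
                new_hi = dhi
            else:
                for i in range(nc):
                    order[i] = i
                for i in range(1, nc):
                    key = order[i]
                    kv = slo[key]
                    p = i - 1
                    while p >= 0 and slo[order[p]] > kv:
                        order[p + 1] = order[p]
                        p -= 1
                    order[p + 1] = key
                has_gap = False
                new_lo = 0.0
                new_hi = 0.0
                cover = dlo
                for i in range(nc):
                    ii = order[i]
                    if slo[ii] > cover + _GAP_TOL:
                        if not has_gap:
                            new_lo = cover
                            has_gap = True
                        new_hi = slo[ii]
                    if shi[ii] > cover:
                        cover = shi[ii]
                if cover < dhi - _GAP_TOL:
                    if not has_gap:
                        new_lo = cover
                        has_gap = True
                    new_hi = dhi
            if has_gap:
                tau[nc] = t
                cst[nc] = C[k - 1, t]
                a0[nc] = 0.0
                a1[nc] = 0.0
                a2[nc] = 0.0
                slo[nc] = new_lo
                shi[nc] = new_hi
                nc += 1
    return C, BP
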