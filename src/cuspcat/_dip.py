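"""Numba kernels for the Hartigan dip statistic.

Everything works in "count" units on the sorted sample x (empirical CDF
steps i -> i+1 at x_i).  A unimodal CDF within sup-distance D = T/(2n) of
the empirical CDF exists iff for some mode index j:

  * the convex branch fits the prefix within the band (left deficiency
    L[j] <= T, measured against the greatest convex minorant of the lower
    step values),
  * the concave branch fits the suffix (right deficiency R[j] <= T, via
    the least concave majorant of the upper step values), and
  * the branches can hand over at x_j: the lowest value attainable by a
    feasible convex branch at x_j (tmin) does not exceed the highest
    value attainable by a feasible concave branch there (rmax).

L is nondecreasing and R nonincreasing in j, so for a given budget T the
candidate modes form a window; tmin/rmax are computed across the window
in one sweep each (tangents over an incremental hull of the upper band,
maximized over candidate chords with a Li Chao line envelope).  The dip
is the smallest feasible T, found by bisection, with the decoupled bound
min_j max(L, R) as a frequently-tight starting point.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-9


@njit(cache=True)
def _deficiency_left(x):
    """L[j] = max_i<=j (i+1 - gcm_j(x_i)): convex-branch deficiency (counts).

    Incremental lower hull of (x_i, i); on each push the deviations over
    the new final segment are rescanned (earlier segments are unchanged),
    with the running prefix maximum stored per hull vertex.
    """
    n = x.shape[0]
    L = np.empty(n)
    hs = np.empty(n, np.int64)  # hull vertex indices
    hm = np.empty(n)  # max deviation over points up to that vertex
    top = 0
    hs[0] = 0
    hm[0] = 1.0
    L[0] = 1.0
    for j in range(1, n):
        while top >= 1:
            o = hs[top - 1]
            a = hs[top]
            # keep a if strictly below chord o -> j
            if (a - o) * (x[j] - x[o]) < (j - o) * (x[a] - x[o]):
                break
            top -= 1
        s = hs[top]
        best = hm[top]
        if x[j] > x[s]:
            slope = (j - s) / (x[j] - x[s])
            for i in range(s + 1, j + 1):
                dev = (i + 1) - (s + slope * (x[i] - x[s]))
                if dev > best:
                    best = dev
            top += 1
            hs[top] = j
            hm[top] = best
        else:  # tied x: the minorant keeps the lower value s; j joins no hull
            for i in range(s + 1, j + 1):
                dev = (i + 1.0) - s
                if dev > best:
                    best = dev
            hm[top] = best
        L[j] = best
    return L


@njit(cache=True)
def _tangent_slope(hx, hy, ht, xq, yq):
    """max over hull vertices h < ht of (yq - hy[h]) / (xq - hx[h]).

    The slope to a fixed point over a convex chain is unimodal; ternary
    search plus a local scan guard.
    """
    lo, hi = 0, ht - 1
    while hi - lo > 2:
        m1 = lo + (hi - lo) // 3
        m2 = hi - (hi - lo) // 3
        s1 = (yq - hy[m1]) / (xq - hx[m1]) if xq > hx[m1] else -np.inf
        s2 = (yq - hy[m2]) / (xq - hx[m2]) if xq > hx[m2] else -np.inf
        if s1 < s2:
            lo = m1 + 1
        else:
            hi = m2 - 1
    best = -np.inf
    for h in range(max(lo - 1, 0), min(hi + 2, ht)):
        if xq > hx[h]:
            s = (yq - hy[h]) / (xq - hx[h])
            if s > best:
                best = s
    return best


@njit(cache=True)
def _lichao_insert(tree, ls, lx, ly, line, node, lo, hi, x):
    """Insert line id into the max Li Chao tree over index range [lo, hi]."""
    while True:
        mid = (lo + hi) // 2
        cur = tree[node]
        if cur < 0:
            tree[node] = line
            return
        xm = x[mid]
        v_new = ly[line] + ls[line] * (xm - lx[line])
        v_cur = ly[cur] + ls[cur] * (xm - lx[cur])
        if v_new > v_cur:
            tree[node] = line
            line, cur = cur, line
        if lo == hi:
            return
        xl = x[lo]
        v_new_l = ly[line] + ls[line] * (xl - lx[line])
        v_cur_l = ly[cur] + ls[cur] * (xl - lx[cur])
        if v_new_l > v_cur_l:
            node = 2 * node + 1
            hi = mid
        else:
            node = 2 * node + 2
            lo = mid + 1


@njit(cache=True)
def _lichao_query(tree, ls, lx, ly, n, x, q):
    node, lo, hi = 0, 0, n - 1
    best = -np.inf
    xq = x[q]
    while True:
        line = tree[node]
        if line >= 0:
            v = ly[line] + ls[line] * (xq - lx[line])
            if v > best:
                best = v
        if lo == hi:
            return best
        mid = (lo + hi) // 2
        if q <= mid:
            node, hi = 2 * node + 1, mid
        else:
            node, lo = 2 * node + 2, mid + 1


@njit(cache=True)
def _tmin_sweep(x, T, jmax):
    """tmin[j], j = 0..jmax: lowest feasible convex-branch value at x_j."""
    n = x.shape[0]
    half = 0.5 * T
    tmin = np.empty(jmax + 1)
    hx = np.empty(n)
    hy = np.empty(n)
    ht = 0
    tree = np.full(4 * n, -1, np.int64)
    ls = np.empty(n)
    lx = np.empty(n)
    ly = np.empty(n)
    for j in range(jmax + 1):
        v = max(j - half, 0.0)
        if j > 0:
            q = _lichao_query(tree, ls, lx, ly, n, x, j)
            if q > v:
                v = q
        tmin[j] = v
        # register point j as a constraint for later modes
        lb = max(j + 1.0 - half, 0.0)
        ub = min(j + half, float(n))
        s = 0.0
        if ht > 0:
            st = _tangent_slope(hx, hy, ht, x[j], lb)
            if st > s:
                s = st
        ls[j] = s
        lx[j] = x[j]
        ly[j] = lb
        _lichao_insert(tree, ls, lx, ly, j, 0, 0, n - 1, x)
        # push (x[j], ub) onto the lower hull of upper-band points
        while ht >= 2:
            if (hy[ht - 1] - hy[ht - 2]) * (x[j] - hx[ht - 2]) < (ub - hy[ht - 2]) * (
                hx[ht - 1] - hx[ht - 2]
            ):
                break
            ht -= 1
        if ht >= 1 and x[j] <= hx[ht - 1]:
            if ub < hy[ht - 1]:  # tie in x: keep the lower band value
                hy[ht - 1] = ub
        else:
            hx[ht] = x[j]
            hy[ht] = ub
            ht += 1
    return tmin


@njit(cache=True)
def _window(L, R, T):
    """Candidate-mode window [jr, jl] where both branch deficiencies fit T."""
    n = L.shape[0]
    jl = -1
    for j in range(n):
        if L[j] <= T + _EPS:
            jl = j
        else:
            break
    jr = n
    for j in range(n - 1, -1, -1):
        if R[j] <= T + _EPS:
            jr = j
        else:
            break
    return jr, jl


@njit(cache=True)
def _feasible(x, xr, L, R, T):
    n = x.shape[0]
    jr, jl = _window(L, R, T)
    if jr > jl:
        return False
    half = 0.5 * T
    tmin = _tmin_sweep(x, T, jl)
    # reflected sweep: rmax[j] = n - tmin_reflected[n-1-j]
    tmin_r = _tmin_sweep(xr, T, n - 1 - jr)
    for j in range(jr, jl + 1):
        rmax = n - tmin_r[n - 1 - j]
        cap = min(j + 1.0 + half, float(n))
        if rmax > cap:
            rmax = cap
        if tmin[j] <= rmax + _EPS:
            return True
    return False


@njit(cache=True)
def _dip_counts(x):
    """Twice the dip times n, exact (bisection to 1e-11 counts)."""
    n = x.shape[0]
    L = _deficiency_left(x)
    xr = -x[::-1].copy()
    R_rev = _deficiency_left(xr)
    R = R_rev[::-1].copy()
    dec = np.inf
    for j in range(n):
        m = L[j] if L[j] > R[j] else R[j]
        if m < dec:
            dec = m
    if _feasible(x, xr, L, R, dec):
        return dec
    lo, hi = dec, 2.0 * float(n)
    while hi - lo > 1e-11:
        mid = 0.5 * (lo + hi)
        if _feasible(x, xr, L, R, mid):
            hi = mid
        else:
            lo = mid
    return hi


@njit(cache=True)
def _dip_at_least(x, T):
    """True iff the dip of the sorted sample x is >= T/(2n) (one feasibility
    check at budget T - 1e-9 instead of a full bisection; used by the
    Monte-Carlo null)."""
    L = _deficiency_left(x)
    xr = -x[::-1].copy()
    R_rev = _deficiency_left(xr)
    R = R_rev[::-1].copy()
    return not _feasible(x, xr, L, R, T - 1e-9)


def dip_counts(x: np.ndarray) -> float:
    return float(_dip_counts(np.ascontiguousarray(x, dtype=np.float64)))


def dip_at_least(x: np.ndarray, T: float) -> bool:
    return bool(_dip_at_least(np.ascontiguousarray(x, dtype=np.float64), float(T)))
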