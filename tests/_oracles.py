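"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: the dip oracle
minimizes the sup-distance to a unimodal CDF directly as a family of
linear programs over mode placements, and the rejection sampler draws
from the quartic-exponential density by accept/reject under a uniform
envelope.  Both are far too slow for production use.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _solve(n_vars, rows):
    A = np.zeros((len(rows), n_vars))
    b = np.zeros(len(rows))
    for r, (coefs, rhs) in enumerate(rows):
        for var, cval in coefs.items():
            A[r, n_vars - 1 if var == "d" else var] = cval
        b[r] = rhs
    c = np.zeros(n_vars)
    c[-1] = 1.0
    bounds = [(0.0, 1.0)] * (n_vars - 1) + [(0.0, None)]
    res = linprog(c, A_ub=A, b_ub=b, bounds=bounds, method="highs")
    return res.fun if res.status == 0 else np.inf


def dip_oracle(sample) -> float:
    """Exact dip of a sample with distinct values, by brute-force LP.

    A unimodal CDF is convex up to its mode and concave after (an atom at
    the mode is allowed).  For every mode placement — at a data point
    with an atom, in a gap (two linking variants), or outside the data —
    the minimal sup-distance is a linear program in the fitted CDF values
    and the distance d; the dip is the minimum over placements.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    assert len(np.unique(x)) == n, "oracle assumes distinct values"
    best = np.inf

    def band(rows, i, var):
        rows.append(({var: -1.0, "d": -1.0}, -(i + 1) / n))
        rows.append(({var: 1.0, "d": -1.0}, i / n))

    def mono(rows, a, b):
        rows.append(({a: 1.0, b: -1.0}, 0.0))

    def convex(rows, i0, i1, i2, xs):
        d01, d12 = xs[1] - xs[0], xs[2] - xs[1]
        rows.append(({i2: -d01, i1: d01 + d12, i0: -d12}, 0.0))

    def concave(rows, i0, i1, i2, xs):
        d01, d12 = xs[1] - xs[0], xs[2] - xs[1]
        rows.append(({i2: d01, i1: -(d01 + d12), i0: d12}, 0.0))

    # gap modes (with the convexity-extends / concavity-extends variants)
    # and the pure-shape edge cases k = -1 (all concave), k = n-1 (all convex)
    for k in range(-1, n):
        variants = [None]
        if 0 <= k <= n - 2:
            variants = []
            if k >= 1:
                variants.append("convex-link")
            if k <= n - 3:
                variants.append("concave-link")
        for variant in variants:
            rows = []
            for i in range(n):
                band(rows, i, i)
            for i in range(n - 1):
                mono(rows, i, i + 1)
            for i in range(1, max(k, 0)):
                if i + 1 <= k:
                    convex(rows, i - 1, i, i + 1, x[i - 1 : i + 2])
            for i in range(k + 2, n - 1):
                concave(rows, i - 1, i, i + 1, x[i - 1 : i + 2])
            if variant == "convex-link":
                convex(rows, k - 1, k, k + 1, x[k - 1 : k + 2])
            if variant == "concave-link":
                concave(rows, k, k + 1, k + 2, x[k : k + 3])
            best = min(best, _solve(n + 1, rows))

    # mode at a data point with an atom: left limit t (slot j), value r (slot n)
    for j in range(n):
        rows = []
        for i in range(n):
            if i != j:
                band(rows, i, i)
        rows.append(({j: -1.0, "d": -1.0}, -j / n))
        rows.append(({j: 1.0, "d": -1.0}, j / n))
        rows.append(({n: -1.0, "d": -1.0}, -(j + 1) / n))
        rows.append(({n: 1.0, "d": -1.0}, (j + 1) / n))
        mono(rows, j, n)
        for i in range(n - 1):
            mono(rows, n if i == j else i, i + 1)
        for i in range(1, j):
            convex(rows, i - 1, i, i + 1, x[i - 1 : i + 2])
        for i in range(j + 2, n - 1):
            concave(rows, i - 1, i, i + 1, x[i - 1 : i + 2])
        if j >= 2:
            convex(rows, j - 2, j - 1, j, x[j - 2 : j + 1])
        if j <= n - 3:
            concave(rows, n, j + 1, j + 2, x[j : j + 3])
        best = min(best, _solve(n + 2, rows))
    return best


def rejection_sample_cusp(alpha: float, beta: float, n: int, rng) -> np.ndarray:
    """Draws from exp(U)/psi by rejection under a uniform envelope on the
    window where the kernel is within 40 log-units of its maximum."""
    from cuspcat import _quad

    lo, hi = _quad.integration_window(np.array([alpha]), np.array([beta]))
    lo, hi = float(lo[0]), float(hi[0])
    roots, _ = _quad.cubic_roots(alpha, beta)
    umax = np.nanmax(
        np.where(np.isnan(roots[0]), -np.inf, _quad.kernel(roots[0], alpha, beta))
    )
    out = np.empty(0)
    while len(out) < n:
        m = max(4 * (n - len(out)), 256)
        y = rng.uniform(lo, hi, size=m)
        keep = rng.uniform(size=m) < np.exp(_quad.kernel(y, alpha, beta) - umax)
        out = np.concatenate([out, y[keep]])
    return out[:n]
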