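"""Vectorized internals for the quartic-exponential stationary density.

Everything here operates on arrays of control values (alpha, beta), one
entry per observation, so the regression likelihood can evaluate log psi
and the density moments for thousands of observations in a handful of
numpy operations.  The public, scalar-facing API lives in ``core``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: log-units below the kernel maximum at which the integration window is cut
KERNEL_DROP = 40.0
#: Gauss-Legendre nodes used for the vectorized likelihood quadrature
DEFAULT_NODES = 128


def kernel(y, alpha, beta):
    """U(y; alpha, beta) = alpha*y + beta*y^2/2 - y^4/4 (broadcasting)."""
    y = np.asarray(y, dtype=float)
    y2 = y * y
    return alpha * y + 0.5 * beta * y2 - 0.25 * y2 * y2


@lru_cache(maxsize=8)
def _leggauss(n: int):
    return np.polynomial.legendre.leggauss(n)


def cubic_roots(alpha, beta):
    """All real stationary points of U: solutions of y^3 - beta*y - alpha = 0.

    Returns ``(roots, n_roots)`` where ``roots`` has shape ``(m, 3)`` sorted
    ascending with trailing NaN where fewer than three real roots exist, and
    ``n_roots`` counts them (1 or 3; boundary double roots are reported as 3
    with two nearly equal entries).  Closed form (trigonometric for the
    three-root case, Cardano otherwise) polished by two Newton steps.
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    alpha, beta = np.broadcast_arrays(alpha, beta)
    m = alpha.shape
    roots = np.full(m + (3,), np.nan)
    delta = 27.0 * alpha**2 - 4.0 * beta**3  # <0 inside bifurcation set

    three = delta < 0  # requires beta > 0
    if np.any(three):
        a3, b3 = alpha[three], beta[three]
        r = 2.0 * np.sqrt(b3 / 3.0)
        arg = np.clip(3.0 * np.sqrt(3.0) * a3 / (2.0 * b3**1.5), -1.0, 1.0)
        phi = np.arccos(arg)
        ks = np.array([0.0, 1.0, 2.0])
        rts = r[:, None] * np.cos((phi[:, None] - 2.0 * np.pi * ks[None, :]) / 3.0)
        roots[three] = np.sort(rts, axis=-1)

    one = ~three
    if np.any(one):
        a1, b1 = alpha[one], beta[one]
        s = np.sqrt(np.maximum(a1**2 / 4.0 - b1**3 / 27.0, 0.0))
        t = np.cbrt(a1 / 2.0 + s) + np.cbrt(a1 / 2.0 - s)
        roots[one, 1] = t

    # Newton polish on y^3 - beta*y - alpha
    for _ in range(2):
        f = roots**3 - beta[..., None] * roots - alpha[..., None]
        fp = 3.0 * roots**2 - beta[..., None]
        step = np.where(np.abs(fp) > 1e-12, f / np.where(fp == 0, 1.0, fp), 0.0)
        roots = roots - np.nan_to_num(step) * ~np.isnan(roots)
    roots = np.sort(roots, axis=-1)  # NaN sort to the end
    n_roots = np.where(three, 3, 1)
    return roots, n_roots


def global_mode(alpha, beta):
    """Global maximizer of the density: the stationary point with largest U."""
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    roots, _ = cubic_roots(alpha, beta)
    u = kernel(roots, alpha[..., None], beta[..., None])
    u = np.where(np.isnan(roots), -np.inf, u)
    idx = np.argmax(u, axis=-1)
    return np.take_along_axis(roots, idx[..., None], axis=-1)[..., 0]


def integration_window(alpha, beta, drop: float = KERNEL_DROP):
    """Per-row interval [lo, hi] outside which exp(U) is negligible.

    The window brackets all stationary points and extends until U falls
    ``drop`` log-units below its global maximum, located by doubling then
    bisection (vectorized).
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    roots, _ = cubic_roots(alpha, beta)
    umax = np.nanmax(
        np.where(np.isnan(roots), -np.inf, kernel(roots, alpha[..., None], beta[..., None])),
        axis=-1,
    )
    target = umax - drop
    left_anchor = np.nanmin(roots, axis=-1)
    right_anchor = np.nanmax(roots, axis=-1)

    def expand(anchor, sign):
        s = np.ones_like(anchor)
        for _ in range(64):
            inside = kernel(anchor + sign * s, alpha, beta) > target
            if not inside.any():
                break
            s = np.where(inside, s * 2.0, s)
        lo_s = np.where(s > 1.0, s / 2.0, 0.0)
        hi_s = s
        for _ in range(30):
            mid = 0.5 * (lo_s + hi_s)
            inside = kernel(anchor + sign * mid, alpha, beta) > target
            lo_s = np.where(inside, mid, lo_s)
            hi_s = np.where(inside, hi_s, mid)
        return anchor + sign * hi_s

    return expand(left_anchor, -1.0), expand(right_anchor, 1.0)


def log_psi_and_moments(alpha, beta, n_nodes: int = DEFAULT_NODES):
    """log psi(alpha, beta) together with E[y] and E[y^2] under the density.

    Fixed-order Gauss-Legendre quadrature on the per-row adaptive window;
    a single (m, n_nodes) kernel evaluation serves all three quantities,
    which is what makes the maximum-likelihood score cheap.
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    lo, hi = integration_window(alpha, beta)
    nodes, weights = _leggauss(n_nodes)
    half = 0.5 * (hi - lo)
    y = 0.5 * (hi + lo)[..., None] + half[..., None] * nodes
    u = kernel(y, alpha[..., None], beta[..., None])
    umax = u.max(axis=-1, keepdims=True)
    w = weights * np.exp(u - umax)
    s0 = w.sum(axis=-1)
    ey = (w * y).sum(axis=-1) / s0
    ey2 = (w * y * y).sum(axis=-1) / s0
    log_psi = np.log(s0 * half) + umax[..., 0]
    return log_psi, ey, ey2
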