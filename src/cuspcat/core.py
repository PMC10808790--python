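"""Deterministic mathematics of the cusp stationary density.

The stochastic cusp model describes an outcome y whose stationary
distribution has log-density kernel

    U(y; alpha, beta) = alpha*y + (1/2)*beta*y**2 - (1/4)*y**4,

so the density is exp(U)/psi with psi the normalizing constant.  alpha is
the asymmetry control (tilts the density), beta the bifurcation control
(beta large enough splits it into two modes).  The sign convention follows
Cobb's estimation tradition: U itself is the exponent, the "physics"
potential is -U.

The discriminant delta = 27*alpha**2 - 4*beta**3 classifies the control
plane: delta < 0 lies inside the bifurcation set (two stable equilibria,
bimodal density), delta > 0 outside (one equilibrium, unimodal),
delta = 0 on the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from . import _quad
from .errors import NumericalError

__all__ = [
    "ControlPoint",
    "EquilibriumSet",
    "StateDensity",
    "MaxwellAmbiguityWarning",
    "log_density_kernel",
    "classify_region",
    "equilibria",
    "normalization_constant",
    "predict_state",
]

#: repeated cubic roots closer than this are merged
ROOT_DEDUP_TOL = 1e-8


class MaxwellAmbiguityWarning(UserWarning):
    """Raised when the Maxwell convention faces an exact density tie."""


def _check_finite(**kwargs):
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ControlPoint:
    """A point (alpha, beta) on the control plane."""

    alpha: float
    beta: float

    def __post_init__(self):
        _check_finite(alpha=self.alpha, beta=self.beta)

    @property
    def delta(self) -> float:
        """Bifurcation-set discriminant 27*alpha^2 - 4*beta^3."""
        return 27.0 * self.alpha**2 - 4.0 * self.beta**3

    @property
    def region(self) -> str:
        return classify_region(self.alpha, self.beta)


@dataclass(frozen=True)
class EquilibriumSet:
    """Stationary points of U at one control point, sorted ascending."""

    roots: tuple[float, ...]
    stability: tuple[str, ...]  # "stable" (mode) or "unstable" (antimode)
    region: str  # "unimodal" | "bimodal" | "boundary"

    @property
    def stable_roots(self) -> tuple[float, ...]:
        return tuple(r for r, s in zip(self.roots, self.stability) if s == "stable")


def log_density_kernel(y, alpha, beta):
    """Evaluate U(y; alpha, beta) = alpha*y + beta*y^2/2 - y^4/4.

    Accepts scalars or arrays (numpy broadcasting); raises ``ValueError``
    on non-finite input.
    """
    _check_finite(y=y, alpha=alpha, beta=beta)
    out = _quad.kernel(np.asarray(y, dtype=float), alpha, beta)
    return float(out) if np.isscalar(y) or np.ndim(y) == 0 else out


def classify_region(alpha: float, beta: float) -> str:
    """Classify a control point relative to the bifurcation set."""
    _check_finite(alpha=alpha, beta=beta)
    delta = 27.0 * alpha**2 - 4.0 * beta**3
    if delta < 0:
        return "bimodal"
    if delta > 0:
        return "unimodal"
    return "boundary"


def equilibria(point: ControlPoint | float, beta: float | None = None) -> EquilibriumSet:
    """Stationary points of the potential: real solutions of alpha + beta*y - y^3 = 0.

    With three distinct roots the outer two are stable modes and the middle
    one the unstable antimode; with a single root it is the unique stable
    mode.  Repeated roots (boundary cases) are deduplicated at tolerance
    ``ROOT_DEDUP_TOL``, and boundary points are treated as unimodal for
    prediction purposes.
    """
    if beta is not None:
        point = ControlPoint(float(point), float(beta))
    roots_arr, _ = _quad.cubic_roots(point.alpha, point.beta)
    roots = [float(r) for r in roots_arr[0] if np.isfinite(r)]
    roots.sort()
    dedup: list[float] = []
    for r in roots:
        if not dedup or abs(r - dedup[-1]) > ROOT_DEDUP_TOL * max(1.0, abs(r)):
            dedup.append(r)
    region = classify_region(point.alpha, point.beta)
    if len(dedup) == 3:
        stability = ("stable", "unstable", "stable")
    elif len(dedup) == 2:  # boundary double root: keep the strict mode only
        u = [float(_quad.kernel(r, point.alpha, point.beta)) for r in dedup]
        dedup = [dedup[int(np.argmax(u))]]
        stability = ("stable",)
    else:
        stability = ("stable",)
    return EquilibriumSet(roots=tuple(dedup), stability=stability, region=region)


def normalization_constant(alpha: float, beta: float, tol: float = 1e-8) -> float:
    """psi(alpha, beta) = integral of exp(U(y; alpha, beta)) over the real line.

    Adaptive quadrature on the window where the kernel is within
    ``_quad.KERNEL_DROP`` log-units of its maximum, with the stationary
    points passed as break points.  Symmetric in the sign of alpha.
    """
    _check_finite(alpha=alpha, beta=beta)
    if not (0.0 < tol <= 1e-3):
        raise ValueError(f"tol must lie in (0, 1e-3], got {tol}")
    lo, hi = _quad.integration_window(alpha, beta)
    lo, hi = float(lo[0]), float(hi[0])
    eq = equilibria(ControlPoint(alpha, beta))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", integrate.IntegrationWarning)
            value, err = integrate.quad(
                lambda y: np.exp(_quad.kernel(y, alpha, beta)),
                lo,
                hi,
                points=[r for r in eq.roots if lo < r < hi],
                epsrel=tol,
                limit=200,
            )
    except integrate.IntegrationWarning as exc:  # pragma: no cover - defensive
        raise NumericalError(
            "normalization integral did not converge",
            diagnostics={"alpha": alpha, "beta": beta, "window": (lo, hi), "cause": str(exc)},
        ) from exc
    if not np.isfinite(value) or value <= 0:
        raise NumericalError(
            "normalization integral returned a non-finite or non-positive value",
            diagnostics={"alpha": alpha, "beta": beta, "value": value, "abserr": err},
        )
    return value


@dataclass
class StateDensity:
    """The normalized stationary density exp(U)/psi at one control point."""

    alpha: float
    beta: float
    psi: float = field(init=False)

    def __post_init__(self):
        self.psi = normalization_constant(self.alpha, self.beta)

    def pdf(self, y):
        return np.exp(_quad.kernel(np.asarray(y, dtype=float), self.alpha, self.beta)) / self.psi

    def logpdf(self, y):
        return _quad.kernel(np.asarray(y, dtype=float), self.alpha, self.beta) - np.log(self.psi)

    def moment(self, order: int) -> float:
        """Raw moment E[y^order] by adaptive quadrature."""
        lo, hi = _quad.integration_window(self.alpha, self.beta)
        value, _ = integrate.quad(
            lambda y: y**order * self.pdf(y), float(lo[0]), float(hi[0]), limit=200
        )
        return value

    def mean(self) -> float:
        return self.moment(1)

    def var(self) -> float:
        m1 = self.moment(1)
        return self.moment(2) - m1 * m1


def predict_state(
    point: ControlPoint,
    convention: str = "delay",
    previous_state: float | None = None,
) -> float:
    """Predicted state at a control point under a fitted-value convention.

    delay
        The stable equilibrium nearest ``previous_state`` (hysteresis-
        respecting; requires ``previous_state``).
    maxwell
        The global maximizer of the density.  An exact tie (alpha = 0 in
        the bimodal region) returns the positive root and emits
        ``MaxwellAmbiguityWarning``; if ``previous_state`` is supplied the
        tie is resolved toward it instead.
    mean
        The density mean, by quadrature.
    """
    eq = equilibria(point)
    stable = np.array(eq.stable_roots)
    if convention == "delay":
        if previous_state is None:
            raise ValueError("delay convention requires previous_state")
        return float(stable[np.argmin(np.abs(stable - previous_state))])
    if convention == "maxwell":
        u = _quad.kernel(stable, point.alpha, point.beta)
        if len(stable) > 1 and abs(u[0] - u[-1]) <= 1e-12 * max(1.0, abs(u[0])):
            if previous_state is not None:
                return float(stable[np.argmin(np.abs(stable - previous_state))])
            warnings.warn(
                "density maxima tie under the Maxwell convention; "
                "returning the positive root",
                MaxwellAmbiguityWarning,
            )
            return float(stable[-1])
        return float(stable[np.argmax(u)])
    if convention == "mean":
        return StateDensity(point.alpha, point.beta).mean()
    raise ValueError(f"unknown convention {convention!r}")
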