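"""Maximum-likelihood cusp catastrophe regression.

The model maps each observation to the control plane and the canonical
state axis through linear submodels

    alpha_i = a0 + a1 * x1_i        (asymmetry; x1 = asymmetry predictor)
    beta_i  = b0 + b1 * x2_i        (bifurcation; x2 = bifurcation predictor)
    z_i     = w0 + w1 * Y_i         (state; Y = observed outcome)

and assigns z_i the cusp stationary density exp(U(z; alpha, beta))/psi.
The log-likelihood in the observed outcome Y includes the Jacobian
log|w1| of the affine state rescaling, which makes log-likelihoods (and
information criteria) comparable with models expressed in outcome units.

The score is available in closed form: the derivatives of log psi with
respect to alpha and beta are the density moments E[y] and E[y^2]/2, so
one quadrature sweep per objective evaluation yields both the likelihood
and its exact gradient.  The (a0, a1, w0, w1) sign flip leaves the
likelihood invariant; fits are canonicalized to w1 > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _quad
from .data import StudyTable
from .errors import DegenerateDataError, IdentifiabilityError, NumericalError

__all__ = [
    "CuspCoefficients",
    "FitConfig",
    "FitResult",
    "negative_log_likelihood",
    "fit_cusp",
    "wald_table",
]

COEF_NAMES = ("a0", "a1", "b0", "b1", "w0", "w1")


@dataclass(frozen=True)
class CuspCoefficients:
    """The six coefficients of the cusp regression.

    ``a0``/``a1`` intercept and slope of the asymmetry submodel, ``b0``/``b1``
    of the bifurcation submodel, ``w0``/``w1`` intercept and scale of the
    state rescaling (``w1 != 0``; the canonical form has ``w1 > 0``).
    """

    a0: float
    a1: float
    b0: float
    b1: float
    w0: float
    w1: float

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"coefficients must be finite, got {vals}")
        if self.w1 == 0.0:
            raise ValueError("w1 must be nonzero")

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.b0, self.b1, self.w0, self.w1])

    @classmethod
    def from_array(cls, theta) -> "CuspCoefficients":
        return cls(*(float(v) for v in theta))

    def alpha(self, x1):
        return self.a0 + self.a1 * np.asarray(x1, dtype=float)

    def beta(self, x2):
        return self.b0 + self.b1 * np.asarray(x2, dtype=float)

    def z(self, y):
        return self.w0 + self.w1 * np.asarray(y, dtype=float)

    def canonical(self) -> "CuspCoefficients":
        """Resolve the sign indeterminacy: flip (a0, a1, w0, w1) if w1 < 0."""
        if self.w1 > 0:
            return self
        return CuspCoefficients(-self.a0, -self.a1, self.b0, self.b1, -self.w0, -self.w1)


@dataclass
class FitConfig:
    """Options shared by the multi-start maximum-likelihood fits."""

    n_starts: int = 10  # heuristic start + (n_starts - 1) seeded perturbations
    seed: int = 0
    maxiter: int = 500
    ftol: float = 1e-9
    n_nodes: int = _quad.DEFAULT_NODES
    perturb_scale: float = 0.5


@dataclass
class FitResult:
    """Estimates, likelihood and Wald inference for one fitted model."""

    model: str  # "cusp" | "linear" | "logistic"
    names: tuple[str, ...]
    estimates: dict[str, float]
    loglik: float
    k: int
    n: int
    covariance: np.ndarray | None
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    ci95_low: dict[str, float]
    ci95_high: dict[str, float]
    converged: bool
    n_starts: int
    best_objective: float
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": self.estimates,
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "best_objective": self.best_objective,
            "extra": {k: v for k, v in self.extra.items() if _jsonable(v)},
        }


def _jsonable(v) -> bool:
    return isinstance(v, (int, float, str, bool, type(None), list, dict))


def wald_inference(names, theta, covariance) -> dict[str, dict[str, float]]:
    """Per-coefficient SE, z, two-sided normal p and 95% CI (1.96*SE)."""
    out = {"se": {}, "z": {}, "p": {}, "ci95_low": {}, "ci95_high": {}}
    diag = None if covariance is None else np.diag(covariance)
    for j, name in enumerate(names):
        est = float(theta[j])
        if diag is None or diag[j] <= 0 or not np.isfinite(diag[j]):
            se = np.nan
        else:
            se = float(np.sqrt(diag[j]))
        if np.isfinite(se) and se > 0:
            zval = est / se
            pval = 2.0 * stats.norm.sf(abs(zval))
        elif est == 0.0:
            zval, pval = 0.0, 1.0
        else:
            zval, pval = np.nan, np.nan
        out["se"][name] = se
        out["z"][name] = float(zval)
        out["p"][name] = float(pval)
        out["ci95_low"][name] = est - 1.96 * se if np.isfinite(se) else np.nan
        out["ci95_high"][name] = est + 1.96 * se if np.isfinite(se) else np.nan
    return out


def _nll_grad(theta: np.ndarray, y: np.ndarray, x1: np.ndarray, x2: np.ndarray, n_nodes: int):
    """Negative log-likelihood and its exact gradient at theta."""
    a0, a1, b0, b1, w0, w1 = theta
    if w1 == 0.0:
        return np.inf, np.zeros(6)
    alpha = a0 + a1 * x1
    beta = b0 + b1 * x2
    z = w0 + w1 * y
    log_psi, ey, ey2 = _quad.log_psi_and_moments(alpha, beta, n_nodes=n_nodes)
    u = _quad.kernel(z, alpha, beta)
    nll = -np.sum(u - log_psi) - len(y) * np.log(abs(w1))
    if not np.isfinite(nll):
        return np.inf, np.zeros(6)
    ra = z - ey
    rb = 0.5 * (z * z - ey2)
    dudz = alpha + beta * z - z**3
    grad = -np.array(
        [
            np.sum(ra),
            np.sum(x1 * ra),
            np.sum(rb),
            np.sum(x2 * rb),
            np.sum(dudz),
            np.sum(y * dudz) + len(y) / w1,
        ]
    )
    if not np.all(np.isfinite(grad)):
        return np.inf, np.zeros(6)
    return nll, grad


def negative_log_likelihood(coeffs: CuspCoefficients, data: StudyTable) -> float:
    """-sum_i [ U(z_i; alpha_i, beta_i) - ln psi(alpha_i, beta_i) + ln|w1| ].

    The ln|w1| Jacobian term makes this a proper negative log-likelihood
    for the observed outcome Y.
    """
    if data.n_analyzed < 1:
        raise ValueError("data must contain at least one row")
    nll, _ = _nll_grad(
        coeffs.as_array(), data.state, data.asymmetry, data.bifurcation, _quad.DEFAULT_NODES
    )
    if not np.isfinite(nll):
        raise NumericalError(
            "negative log-likelihood is non-finite at the supplied coefficients",
            diagnostics={"coefficients": coeffs.as_array().tolist()},
        )
    return float(nll)


def heuristic_start(y, x1, x2) -> np.ndarray:
    """Linear-regression-inspired starting point.

    The outcome is standardized (w0, w1 from its mean/SD); a1 and b1 start
    at the standardized multiple-regression slopes of the outcome on the
    two predictors, with intercepts centering the controls at zero.
    """
    sy = np.std(y)
    w1 = 1.0 / sy
    w0 = -np.mean(y) / sy
    X = np.column_stack([np.ones_like(x1), x1, x2])
    coef, *_ = np.linalg.lstsq(X, (y - np.mean(y)) / sy, rcond=None)
    a1 = coef[1]
    b1 = coef[2]
    a0 = -a1 * np.mean(x1)
    b0 = -b1 * np.mean(x2)
    return np.array([a0, a1, b0, b1, w0, w1])


def _validate_for_fit(data: StudyTable, min_rows: int = 20):
    if data.n_analyzed < min_rows:
        raise ValueError(f"need at least {min_rows} rows, got {data.n_analyzed}")
    if np.ptp(data.state) == 0.0:
        raise DegenerateDataError("state column is constant; no fit is possible")
    for role in ("asymmetry", "bifurcation"):
        col = getattr(data, role)
        if np.ptp(col) == 0.0:
            raise IdentifiabilityError(
                f"{role} column {data.roles[role]!r} is constant; "
                f"its slope is not identifiable"
            )


def hessian_fd(grad_fn, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Symmetrized central finite differences of an analytic gradient."""
    k = len(theta)
    H = np.zeros((k, k))
    for j in range(k):
        h = rel_step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def covariance_from_hessian(H: np.ndarray):
    """Inverse observed information; (cov, ok). Falls back to pseudo-inverse."""
    try:
        cov = np.linalg.inv(H)
        if np.all(np.diag(cov) > 0):
            return cov, True
    except np.linalg.LinAlgError:
        pass
    warnings.warn(
        "observed information is singular or indefinite; "
        "Wald inference uses a pseudo-inverse and may be unreliable",
        UserWarning,
    )
    return np.linalg.pinv(H), False


def fit_cusp(data: StudyTable, config: FitConfig | None = None) -> FitResult:
    """Fit the cusp regression by multi-start quasi-Newton maximum likelihood.

    Starts from the linear-regression heuristic plus seeded random
    perturbations; the reported optimum is the best across starts (hence
    never worse than the heuristic starting point).  Wald inference comes
    from the inverse observed Hessian at the canonicalized optimum.
    """
    config = config or FitConfig()
    _validate_for_fit(data)
    y, x1, x2 = data.state, data.asymmetry, data.bifurcation
    rng = np.random.default_rng(config.seed)

    def fun(theta):
        return _nll_grad(theta, y, x1, x2, config.n_nodes)

    theta0 = heuristic_start(y, x1, x2)
    starts = [theta0]
    for _ in range(max(0, config.n_starts - 1)):
        scale = config.perturb_scale * np.maximum(np.abs(theta0), 0.2)
        starts.append(theta0 + rng.normal(size=6) * scale)

    results = []
    for s in starts:
        res = optimize.minimize(
            fun,
            s,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": config.maxiter, "ftol": config.ftol},
        )
        results.append(res)
    finite = [r for r in results if np.isfinite(r.fun)]
    if not finite:
        raise NumericalError(
            "cusp optimization failed from every start",
            diagnostics={"messages": [str(r.message) for r in results]},
        )
    best = min(finite, key=lambda r: r.fun)
    converged = bool(best.success) or best.fun <= fun(theta0)[0]

    coeffs = CuspCoefficients.from_array(best.x).canonical()
    theta = coeffs.as_array()
    H = hessian_fd(lambda t: fun(t)[1], theta)
    cov, cov_ok = covariance_from_hessian(H)
    inference = wald_inference(COEF_NAMES, theta, cov)
    return FitResult(
        model="cusp",
        names=COEF_NAMES,
        estimates={n: float(v) for n, v in zip(COEF_NAMES, theta)},
        loglik=-float(best.fun),
        k=6,
        n=data.n_analyzed,
        covariance=cov,
        converged=converged,
        n_starts=len(starts),
        best_objective=float(best.fun),
        extra={
            "cov_ok": cov_ok,
            "start_objectives": [float(r.fun) for r in results],
            "heuristic_start": theta0.tolist(),
        },
        **inference,
    )


def wald_table(fit: FitResult, significance: float = 0.01) -> pd.DataFrame:
    """Coefficient table: estimate, SE, z, p, 95% CI and a significance flag.

    The default significance level is 0.01.  If the covariance was
    unavailable the inference columns are NaN (a warning was already
    raised when the fit was produced).
    """
    if not (0.0 < significance < 0.5):
        raise ValueError("significance must lie in (0, 0.5)")
    rows = []
    for name in fit.names:
        est = fit.estimates[name]
        p = fit.p.get(name, np.nan)
        rows.append(
            {
                "term": name,
                "estimate": est,
                "ci95_low": fit.ci95_low.get(name, np.nan),
                "ci95_high": fit.ci95_high.get(name, np.nan),
                "se": fit.se.get(name, np.nan),
                "z": fit.z.get(name, np.nan),
                "p": p,
                "significant": bool(p < significance) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)
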