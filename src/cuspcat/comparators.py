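"""Competing models: Gaussian multiple regression and the S-shaped logistic.

Both are fitted by maximum likelihood on the same study table as the cusp
model.  The linear model is ordinary least squares with all predictors
entered in one step (k = 4 free parameters: intercept, two slopes, sigma).
The logistic alternative keeps the cusp's control submodels but runs them
through an S-curve mean

    E[Y*_i] = 1 / (1 + exp(-alpha_i / beta_i**2)),

with Gaussian error and the outcome min-max rescaled to [0, 1] for the
fit (k = 5).  No published equation exists for this comparator beyond the
convention of the estimation tradition it comes from; the reported
log-likelihood is transformed back to raw outcome units (the rescaling's
Jacobian) so it is comparable with the other two models.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit, logit

from .data import StudyTable
from .errors import DegenerateDataError, IdentifiabilityError, NumericalError
from .regression import FitConfig, FitResult, hessian_fd, wald_inference

__all__ = ["fit_linear", "fit_logistic"]

LINEAR_NAMES = ("intercept", "slope_asymmetry", "slope_bifurcation", "sigma")
LOGISTIC_NAMES = ("a0", "a1", "b0", "b1", "sigma")

_BETA_SQ_FLOOR = 1e-8


def fit_linear(data: StudyTable) -> FitResult:
    """Gaussian linear regression of the outcome on both predictors.

    Exact least squares (via statsmodels OLS); the log-likelihood is the
    Gaussian MLE value with sigma^2 = RSS/n, so k = 4.
    """
    if data.n_analyzed < 5:
        raise ValueError("need at least 5 rows")
    y, x1, x2 = data.state, data.asymmetry, data.bifurcation
    if np.ptp(y) == 0.0:
        raise DegenerateDataError("outcome is constant; degenerate linear fit")
    X = sm.add_constant(np.column_stack([x1, x2]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise IdentifiabilityError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    rss = float(np.sum(res.resid**2))
    if rss == 0.0:
        raise DegenerateDataError("zero residual variance; degenerate linear fit")
    n = data.n_analyzed
    sigma = np.sqrt(rss / n)
    estimates = dict(zip(LINEAR_NAMES, (*res.params, sigma)))
    # coefficient covariance from OLS; sigma left without Wald inference
    cov = np.full((4, 4), np.nan)
    cov[:3, :3] = np.asarray(res.cov_params())
    theta = np.array(list(estimates.values()))
    inference = wald_inference(LINEAR_NAMES, theta, cov)
    return FitResult(
        model="linear",
        names=LINEAR_NAMES,
        estimates={k: float(v) for k, v in estimates.items()},
        loglik=float(res.llf),
        k=4,
        n=n,
        covariance=cov,
        converged=True,
        n_starts=1,
        best_objective=-float(res.llf),
        extra={"rss": rss},
        **inference,
    )


def _logistic_rss(theta, ys, x1, x2):
    a0, a1, b0, b1 = theta
    beta_sq = (b0 + b1 * x2) ** 2
    clamped = beta_sq < _BETA_SQ_FLOOR
    mean = expit((a0 + a1 * x1) / np.maximum(beta_sq, _BETA_SQ_FLOOR))
    rss = float(np.sum((ys - mean) ** 2))
    return rss, bool(np.any(clamped))


def fit_logistic(data: StudyTable, config: FitConfig | None = None) -> FitResult:
    """Fit the logistic comparator by multi-start Gaussian maximum likelihood.

    Shares the multi-start policy (and seed) of the cusp fit.  Vanishing
    beta_i^2 denominators are floored at 1e-8 and flagged.  ``loglik`` is
    in raw outcome units; the rescaled-outcome value is in
    ``extra["loglik_rescaled"]``.
    """
    config = config or FitConfig()
    if data.n_analyzed < 5:
        raise ValueError("need at least 5 rows")
    y, x1, x2 = data.state, data.asymmetry, data.bifurcation
    y_range = float(np.ptp(y))
    if y_range == 0.0:
        raise DegenerateDataError("outcome is constant; degenerate logistic fit")
    ys = (y - y.min()) / y_range
    n = data.n_analyzed
    rng = np.random.default_rng(config.seed)

    def fun(theta):
        return _logistic_rss(theta, ys, x1, x2)[0]

    # heuristic start: logit-linearized regression; plus the constant-mean
    # solution (nested model) and seeded perturbations
    s = logit(np.clip(ys, 0.01, 0.99))
    X = np.column_stack([np.ones(n), x1, x2])
    coef, *_ = np.linalg.lstsq(X, s, rcond=None)
    theta0 = np.array([coef[0], coef[1], 1.0, 0.0])
    const_start = np.array([float(logit(np.clip(ys.mean(), 0.01, 0.99))), 0.0, 1.0, 0.0])
    starts = [theta0, const_start]
    for _ in range(max(0, config.n_starts - 2)):
        scale = config.perturb_scale * np.maximum(np.abs(theta0), 0.2)
        starts.append(theta0 + rng.normal(size=4) * scale)

    results = []
    for st in starts:
        res = optimize.minimize(fun, st, method="L-BFGS-B",
                                options={"maxiter": config.maxiter, "ftol": config.ftol})
        results.append(res)
    finite = [r for r in results if np.isfinite(r.fun)]
    if not finite:
        raise NumericalError(
            "logistic optimization failed from every start",
            diagnostics={"messages": [str(r.message) for r in results]},
        )
    best = min(finite, key=lambda r: r.fun)
    rss, clamped = _logistic_rss(best.x, ys, x1, x2)
    if rss == 0.0:
        raise DegenerateDataError("zero residual variance in the logistic fit")
    sigma = np.sqrt(rss / n)
    loglik_rescaled = -0.5 * n * (np.log(2.0 * np.pi * sigma**2) + 1.0)
    loglik_raw = loglik_rescaled - n * np.log(y_range)

    # Wald inference from the observed information of the profiled Gaussian NLL
    def nll(theta):
        r, _ = _logistic_rss(theta, ys, x1, x2)
        return 0.5 * n * np.log(r / n)

    def grad(theta):
        return optimize.approx_fprime(theta, nll, 1e-6 * np.maximum(np.abs(theta), 1.0))

    # the mean 1/(1+exp(-alpha/beta^2)) is invariant under the scale flow
    # (a, b^2) -> (c*a, c*b^2), so the k = 5 convention carries one flat
    # direction; inference uses the pseudo-inverse of the observed
    # information along the identified directions
    H = hessian_fd(grad, np.asarray(best.x), rel_step=1e-4)
    cov4 = np.linalg.pinv(H)
    cov_ok = bool(np.all(np.isfinite(cov4)))
    cov = np.full((5, 5), np.nan)
    cov[:4, :4] = cov4
    theta_full = np.append(best.x, sigma)
    inference = wald_inference(LOGISTIC_NAMES, theta_full, cov)
    return FitResult(
        model="logistic",
        names=LOGISTIC_NAMES,
        estimates={k: float(v) for k, v in zip(LOGISTIC_NAMES, theta_full)},
        loglik=float(loglik_raw),
        k=5,
        n=n,
        covariance=cov,
        converged=bool(best.success),
        n_starts=len(starts),
        best_objective=float(best.fun),
        extra={
            "loglik_rescaled": float(loglik_rescaled),
            "outcome_range": y_range,
            "beta_floor_active": clamped,
            "cov_ok": cov_ok,
            "rss_rescaled": rss,
        },
        **inference,
    )
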