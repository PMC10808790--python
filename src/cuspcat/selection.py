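"""Model comparison: information criteria, likelihood-ratio test, diagnostics.

AIC = 2k - 2*loglik, AICc = AIC + 2k(k+1)/(n-k-1), BIC = k*ln(n) - 2*loglik.
The chi-square difference test contrasts nested fits (here linear vs cusp)
with df equal to the difference in parameter counts.  Parameter counts can
be overridden so printed comparison tables from other conventions (e.g. a
7-parameter cusp count) can be replayed verbatim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _quad
from .comparators import fit_linear, fit_logistic
from .data import StudyTable
from .regression import CuspCoefficients, FitConfig, FitResult, fit_cusp

__all__ = [
    "information_criteria",
    "likelihood_ratio",
    "likelihood_ratio_test",
    "LikelihoodRatioResult",
    "fit_diagnostics",
    "DiagnosticsBundle",
    "compare_models",
    "ComparisonResult",
]


def information_criteria(loglik: float, k: int, n: int | None = None) -> dict[str, float]:
    """AIC, and AICc/BIC when a sample size is supplied (requires n > k + 1)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    out = {"AIC": 2.0 * k - 2.0 * loglik}
    if n is not None:
        if k > 0 and n <= k + 1:
            raise ValueError(f"AICc requires n > k + 1, got n={n}, k={k}")
        out["AICc"] = out["AIC"] + (2.0 * k * (k + 1) / (n - k - 1) if k > 0 else 0.0)
        out["BIC"] = k * np.log(n) - 2.0 * loglik if n > 0 else 0.0
    return out


@dataclass(frozen=True)
class LikelihoodRatioResult:
    chi2: float
    df: int
    p: float


def likelihood_ratio(
    loglik_simple: float, k_simple: int, loglik_complex: float, k_complex: int
) -> LikelihoodRatioResult:
    """Chi-square difference test from raw log-likelihoods and counts."""
    if k_complex <= k_simple:
        raise ValueError("the complex model must have more parameters")
    chi2 = 2.0 * (loglik_complex - loglik_simple)
    if chi2 < 0:
        warnings.warn(
            "complex model fits worse than the simple one; chi2 clamped at 0 "
            "(misfit indicator)",
            UserWarning,
        )
        chi2 = 0.0
    df = k_complex - k_simple
    return LikelihoodRatioResult(chi2=float(chi2), df=df, p=float(stats.chi2.sf(chi2, df)))


def likelihood_ratio_test(fit_simple: FitResult, fit_complex: FitResult) -> LikelihoodRatioResult:
    """Likelihood-ratio contrast of two nested fits on the same data."""
    if fit_simple.n != fit_complex.n:
        raise ValueError("fits must share the same sample")
    return likelihood_ratio(fit_simple.loglik, fit_simple.k, fit_complex.loglik, fit_complex.k)


@dataclass
class DiagnosticsBundle:
    """Delay-convention fitted values and companions for a cusp fit."""

    fitted: np.ndarray  # canonical state units (z)
    residuals: np.ndarray
    pseudo_r2: float
    in_bifurcation: np.ndarray
    n_in_bifurcation: int
    resid_fitted_corr: float

    def to_dict(self) -> dict:
        return {
            "pseudo_r2": self.pseudo_r2,
            "n_in_bifurcation": self.n_in_bifurcation,
            "resid_fitted_corr": self.resid_fitted_corr,
            "n": int(len(self.fitted)),
        }


def delay_fitted(coeffs: CuspCoefficients, data: StudyTable) -> np.ndarray:
    """Per-row stable equilibrium nearest the observed rescaled state."""
    alpha = coeffs.alpha(data.asymmetry)
    beta = coeffs.beta(data.bifurcation)
    z = coeffs.z(data.state)
    roots, n_roots = _quad.cubic_roots(alpha, beta)
    # stable roots: the outer pair when three, else the single root (col 0)
    lo_root = roots[:, 0]
    hi_root = np.where(n_roots == 3, roots[:, 2], roots[:, 0])
    pick_hi = np.abs(hi_root - z) < np.abs(lo_root - z)
    return np.where(pick_hi, hi_root, lo_root)


def fit_diagnostics(fit: FitResult, data: StudyTable) -> DiagnosticsBundle:
    """Residual diagnostics for a converged cusp fit.

    Fitted values use the delay convention with the observed state as the
    previous state; residuals are in canonical (z) units.  The pseudo-R^2
    is 1 - Var(residual)/Var(z).  Bifurcation-set membership of each
    observation's control point is reported alongside.
    """
    if fit.model != "cusp":
        raise ValueError("diagnostics are defined for cusp fits")
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    coeffs = CuspCoefficients(**{k: fit.estimates[k] for k in fit.names})
    z = coeffs.z(data.state)
    fitted = delay_fitted(coeffs, data)
    residuals = z - fitted
    var_z = float(np.var(z))
    pseudo_r2 = 1.0 - float(np.var(residuals)) / var_z if var_z > 0 else np.nan
    alpha = coeffs.alpha(data.asymmetry)
    beta = coeffs.beta(data.bifurcation)
    inside = 27.0 * alpha**2 - 4.0 * beta**3 < 0
    if np.ptp(fitted) > 0 and np.ptp(residuals) > 0:
        corr = float(np.corrcoef(residuals, fitted)[0, 1])
    else:
        corr = np.nan
    return DiagnosticsBundle(
        fitted=fitted,
        residuals=residuals,
        pseudo_r2=pseudo_r2,
        in_bifurcation=inside,
        n_in_bifurcation=int(inside.sum()),
        resid_fitted_corr=corr,
    )


@dataclass
class ComparisonResult:
    """Table-style comparison of the three fitted models plus the LR test."""

    table: pd.DataFrame
    fits: dict[str, FitResult]
    lr_linear_vs_cusp: LikelihoodRatioResult
    best: dict[str, str]  # criterion -> model name with the smallest value

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "lr_linear_vs_cusp": {
                "chi2": self.lr_linear_vs_cusp.chi2,
                "df": self.lr_linear_vs_cusp.df,
                "p": self.lr_linear_vs_cusp.p,
            },
            "best": self.best,
        }


def comparison_row(name: str, loglik: float, k: int, n: int) -> dict:
    ic = information_criteria(loglik, k, n)
    return {"model": name, "loglik": loglik, "k": k, **ic}


def compare_models(
    data: StudyTable,
    config: FitConfig | None = None,
    k_override: dict[str, int] | None = None,
) -> ComparisonResult:
    """Fit linear, logistic and cusp models (shared seeds) and compare them.

    ``k_override`` maps model names to alternative parameter counts; the
    table then carries both the internal count (``k``) and the override
    (``k_used``) actually entered into the criteria.
    """
    config = config or FitConfig()
    fits = {
        "linear": fit_linear(data),
        "logistic": fit_logistic(data, config),
        "cusp": fit_cusp(data, config),
    }
    k_override = k_override or {}
    rows = []
    for name in ("linear", "logistic", "cusp"):
        f = fits[name]
        k_used = int(k_override.get(name, f.k))
        row = comparison_row(name, f.loglik, k_used, f.n)
        row["k"] = f.k
        row["k_used"] = k_used
        rows.append(row)
    table = pd.DataFrame(rows, columns=["model", "loglik", "k", "k_used", "AIC", "AICc", "BIC"])
    best = {c: str(table.loc[table[c].idxmin(), "model"]) for c in ("AIC", "AICc", "BIC")}
    lr = likelihood_ratio_test(fits["linear"], fits["cusp"])
    return ComparisonResult(table=table, fits=fits, lr_linear_vs_cusp=lr, best=best)
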