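"""Cusp maximum-likelihood regression: likelihood, fitting, Wald inference."""

import numpy as np
import pytest

from cuspcat.core import normalization_constant
from cuspcat.data import StudyTable
from cuspcat.errors import DegenerateDataError, IdentifiabilityError
from cuspcat.regression import (
    CuspCoefficients,
    FitConfig,
    FitResult,
    fit_cusp,
    heuristic_start,
    negative_log_likelihood,
    wald_table,
    wald_inference,
)
from cuspcat.synthetic import SyntheticSpec, generate_study

from conftest import TRUTH


def table_from(y, x1, x2):
    return StudyTable.from_arrays(y, x1, x2)


class TestNegativeLogLikelihood:
    def test_single_row_closed_form(self):
        # one row at the origin with identity submodels: NLL = ln psi(0, 0)
        tab = table_from([0.0, 1.0], [0.0, 1.0], [0.0, 1.0])
        one = StudyTable(tab.data.iloc[:1], tab.roles, 1, ())
        coeffs = CuspCoefficients(0.0, 1.0, 0.0, 1.0, 0.0, 1.0)
        expected = np.log(normalization_constant(0.0, 0.0))
        assert negative_log_likelihood(coeffs, one) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.9417, abs=5e-4)

    def test_sign_flip_invariance(self, small_table):
        c = CuspCoefficients(0.4, -0.2, 0.1, 0.05, 1.0, 0.5)
        flipped = CuspCoefficients(-0.4, 0.2, 0.1, 0.05, -1.0, -0.5)
        assert negative_log_likelihood(c, small_table) == pytest.approx(
            negative_log_likelihood(flipped, small_table), rel=1e-12
        )

    def test_outcome_shift_compensated_by_w0(self, small_table):
        c = CuspCoefficients(0.4, -0.2, 0.1, 0.05, 1.0, 0.5)
        shift = 3.7
        shifted = StudyTable.from_arrays(
            small_table.state + shift, small_table.asymmetry, small_table.bifurcation
        )
        c2 = CuspCoefficients(0.4, -0.2, 0.1, 0.05, 1.0 - 0.5 * shift, 0.5)
        assert negative_log_likelihood(c, small_table) == pytest.approx(
            negative_log_likelihood(c2, shifted), rel=1e-9
        )

    def test_w1_zero_rejected(self):
        with pytest.raises(ValueError):
            CuspCoefficients(0, 0, 0, 0, 0, 0.0)


class TestFitCusp:
    def test_recovers_generating_coefficients(self, fast_config):
        tab = generate_study(SyntheticSpec(n=1500, coefficients=TRUTH, seed=42))
        fit = fit_cusp(tab, fast_config)
        assert fit.converged
        assert fit.estimates["w1"] > 0  # canonical form
        # single-replicate check at ~4 SE slack; the acceptance suite runs
        # the full 20-replicate recovery experiment
        for name, true_val in [("a1", TRUTH.a1), ("b1", TRUTH.b1), ("w1", TRUTH.w1)]:
            assert fit.estimates[name] == pytest.approx(
                true_val, abs=4 * fit.se[name] + 1e-6
            )

    def test_optimum_not_worse_than_heuristic_start(self, small_table, fast_config):
        fit = fit_cusp(small_table, fast_config)
        theta0 = heuristic_start(
            small_table.state, small_table.asymmetry, small_table.bifurcation
        )
        nll0 = negative_log_likelihood(CuspCoefficients.from_array(theta0), small_table)
        assert fit.best_objective <= nll0 + 1e-9

    def test_constant_bifurcation_column_is_identifiability_error(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning):
            tab = table_from(rng.normal(size=50), rng.normal(size=50), np.full(50, 7.0))
        with pytest.raises(IdentifiabilityError, match="disorder"):
            fit_cusp(tab)

    def test_constant_state_is_degenerate(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning):
            tab = table_from(np.full(50, 1.0), rng.normal(size=50), rng.normal(size=50))
        with pytest.raises(DegenerateDataError):
            fit_cusp(tab)

    def test_too_few_rows(self):
        rng = np.random.default_rng(0)
        tab = table_from(rng.normal(size=10), rng.normal(size=10), rng.normal(size=10))
        with pytest.raises(ValueError):
            fit_cusp(tab)


def test_se_calibration_against_replicate_spread():
    """Across seeded replicates the reported Wald SEs track the empirical
    sampling spread of the estimates (within 30%)."""
    ests, ses = [], []
    for rep in range(50):
        tab = generate_study(SyntheticSpec(n=1000, coefficients=TRUTH, seed=5000 + rep))
        fit = fit_cusp(tab, FitConfig(n_starts=2, seed=rep))
        ests.append([fit.estimates[k] for k in ("a1", "b1", "w1")])
        ses.append([fit.se[k] for k in ("a1", "b1", "w1")])
    ests, ses = np.array(ests), np.array(ses)
    for j in range(3):
        empirical = ests[:, j].std(ddof=1)
        reported = ses[:, j].mean()
        assert 0.7 < empirical / reported < 1.3


class TestWaldTable:
    def _fake_fit(self, estimates, ses):
        names = tuple(estimates)
        theta = np.array(list(estimates.values()))
        cov = np.diag(np.array(list(ses.values())) ** 2)
        inference = wald_inference(names, theta, cov)
        return FitResult(
            model="cusp", names=names, estimates=estimates, loglik=0.0, k=len(names),
            n=100, covariance=cov, converged=True, n_starts=1, best_objective=0.0,
            **inference,
        )

    def test_published_inference_rows(self):
        # the asymmetry slope row: 0.331 (SE 0.028) -> z ~ 11.8, CI ~ (0.276, 0.386)
        fit = self._fake_fit({"a1": 0.331, "b1": 0.112}, {"a1": 0.028, "b1": 0.005})
        tab = wald_table(fit, significance=0.01).set_index("term")
        assert tab.loc["a1", "z"] == pytest.approx(11.82, abs=0.02)
        assert tab.loc["a1", "ci95_low"] == pytest.approx(0.276, abs=0.002)
        assert tab.loc["a1", "ci95_high"] == pytest.approx(0.386, abs=0.002)
        # the bifurcation slope row: 0.112 (SE 0.005) -> CI ~ (0.102, 0.122)
        assert tab.loc["b1", "ci95_low"] == pytest.approx(0.102, abs=0.001)
        assert tab.loc["b1", "ci95_high"] == pytest.approx(0.122, abs=0.001)
        assert bool(tab.loc["a1", "significant"]) and bool(tab.loc["b1", "significant"])

    def test_zero_estimate(self):
        fit = self._fake_fit({"a1": 0.0}, {"a1": 0.5})
        tab = wald_table(fit).set_index("term")
        assert tab.loc["a1", "z"] == 0.0
        assert tab.loc["a1", "p"] == 1.0
        assert not tab.loc["a1", "significant"]

    def test_significance_validated(self, small_table, fast_config):
        fit = fit_cusp(small_table, fast_config)
        with pytest.raises(ValueError):
            wald_table(fit, significance=0.7)
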