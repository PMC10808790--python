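import numpy as np
import pytest

from cuspcat.regression import CuspCoefficients, FitConfig
from cuspcat.synthetic import SyntheticSpec, generate_study

TRUTH = CuspCoefficients(a0=-3.015, a1=0.331, b0=-1.453, b1=0.112, w0=-3.522, w1=0.364)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_table():
    """A quick study table (n = 600) generated from the preset coefficients."""
    return generate_study(SyntheticSpec(n=600, coefficients=TRUTH, seed=7))


@pytest.fixture(scope="session")
def fast_config():
    return FitConfig(n_starts=3, seed=0)


@pytest.fixture(scope="session")
def recovery():
    """The 20-replicate generate-and-refit experiment at study scale
    (n = 2,420, published coefficients as generating truth), shared by the
    acceptance checks and the model-ordering tests."""
    from cuspcat.recovery import recovery_experiment

    return recovery_experiment(n_replicates=20, seed=2026, fit_comparators=True)
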