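"""Dip test, Silverman critical bandwidth, mode counting, SiZer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuspcat.modality import (
    SIZER_CLASSES,
    count_modes,
    critical_bandwidth,
    dip_statistic,
    dip_test,
    mode_ladder,
    silverman_test,
    sizer_map,
)

from _oracles import dip_oracle


def bimodal(rng, n=500, sep=3.0, sd=1.0):
    half = n // 2
    return np.concatenate(
        [rng.normal(-sep, sd, half), rng.normal(sep, sd, n - half)]
    )


class TestDipStatistic:
    def test_two_points(self):
        assert dip_statistic([0.0, 1.0]) == pytest.approx(0.25, abs=1e-12)

    def test_constant_sample(self):
        assert dip_statistic([2.0, 2.0, 2.0]) == 0.0

    def test_matches_exhaustive_small_n_oracle(self, rng):
        for trial in range(40):
            n = int(rng.integers(2, 9))
            if trial % 3 == 0:
                s = rng.uniform(size=n)
            elif trial % 3 == 1:
                s = np.concatenate(
                    [rng.normal(-2, 0.1, max(1, n // 2)), rng.normal(2, 0.1, n - max(1, n // 2))]
                )
            else:
                s = rng.normal(size=n)
            s = np.unique(np.round(s, 6))
            if len(s) < 2:
                continue
            assert dip_statistic(s) == pytest.approx(dip_oracle(s), abs=1e-9)

    def test_clustered_duplicates(self):
        # two point masses: the largest possible dip
        assert dip_statistic([0.0, 0.0, 1.0, 1.0]) == pytest.approx(0.25, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=60))
    def test_lower_bound_half_over_n(self, sample):
        s = np.asarray(sample)
        if np.ptp(s) == 0.0:
            return
        assert dip_statistic(s) >= 1.0 / (2 * len(s)) - 1e-12

    def test_separated_mixture_is_large(self, rng):
        assert dip_statistic(bimodal(rng, n=500)) > 0.05

    def test_rejects_tiny_or_bad_input(self):
        with pytest.raises(ValueError):
            dip_statistic([1.0])
        with pytest.raises(ValueError):
            dip_statistic([0.0, np.nan])


class TestDipTest:
    def test_mixture_strongly_rejected(self, rng):
        res = dip_test(bimodal(rng, n=500), n_mc=1999, seed=11)
        assert res.p < 0.001

    def test_uniform_not_rejected(self, rng):
        res = dip_test(rng.uniform(size=500), n_mc=499, seed=3)
        assert res.p > 0.05

    def test_deterministic_under_seed(self, rng):
        s = rng.normal(size=120)
        a = dip_test(s, n_mc=199, seed=42)
        b = dip_test(s, n_mc=199, seed=42)
        assert a == b

    def test_null_p_values_approximately_uniform(self):
        # dip p-values computed on true-null (uniform) data should be ~U(0,1)
        rng = np.random.default_rng(99)
        ps = [
            dip_test(rng.uniform(size=50), n_mc=199, seed=int(rng.integers(2**31))).p
            for _ in range(200)
        ]
        ps = np.sort(ps)
        ks = np.max(np.abs(ps - (np.arange(1, 201)) / 200.0))
        assert ks < 0.1


class TestSilverman:
    def test_critical_bandwidth_two_equal_gaussians(self):
        # the KDE of {-1, +1} is a two-Gaussian mixture: unimodal iff h >= 1
        assert critical_bandwidth([-1.0, 1.0], k=1) == pytest.approx(1.0, abs=5e-3)

    def test_h_crit_monotone_in_k(self, rng):
        s = bimodal(rng, n=200)
        h1 = critical_bandwidth(s, 1)
        h2 = critical_bandwidth(s, 2)
        h3 = critical_bandwidth(s, 3)
        assert h2 <= h1 + 1e-9 and h3 <= h2 + 1e-9

    def test_mode_count_brackets_h_crit(self, rng):
        s = rng.normal(size=150)
        for k in (1, 2):
            h = critical_bandwidth(s, k)
            assert count_modes(s, h) <= k
            assert count_modes(s, h * 0.98) > k

    def test_mixture_rejected_gaussian_not(self, rng):
        res_mix = silverman_test(bimodal(rng, n=400), k_null=1, n_boot=400, seed=5)
        assert res_mix.p < 0.01
        res_gauss = silverman_test(rng.normal(size=500), k_null=1, n_boot=400, seed=6)
        assert res_gauss.p > 0.05

    def test_type_one_error_not_badly_inflated(self):
        """Known anti-conservative tendency tolerated up to ~1.5x nominal
        (plus Monte-Carlo slack at 100 replicates)."""
        rng = np.random.default_rng(1234)
        rejections = 0
        for rep in range(100):
            s = rng.normal(size=200)
            res = silverman_test(s, k_null=1, n_boot=200, seed=rep)
            rejections += res.p <= 0.05
        assert rejections / 100 <= 0.15

    def test_degenerate_sample_errors(self):
        with pytest.raises(ValueError):
            silverman_test(np.full(50, 3.0))

    def test_mode_ladder_stops_at_first_retained_k(self, rng):
        s = bimodal(rng, n=300)
        k_sel, ladder = mode_ladder(s, n_boot=200, seed=8)
        assert k_sel is not None and k_sel >= 2
        assert all(r.p <= 0.05 for r in ladder[:-1])
        assert ladder[-1].p > 0.05
        hs = [r.h_crit for r in ladder]
        assert all(a >= b - 1e-9 for a, b in zip(hs, hs[1:]))


class TestCountModes:
    def test_two_points_by_bandwidth(self):
        assert count_modes([-1.0, 1.0], bandwidth=0.3) == 2
        assert count_modes([-1.0, 1.0], bandwidth=2.0) == 1

    def test_single_repeated_value(self):
        assert count_modes([5.0] * 20) == 1

    def test_matches_direct_kde_scan(self, rng):
        s = bimodal(rng, n=200, sep=2.5)
        h = 0.8
        grid = np.linspace(s.min() - 3 * h, s.max() + 3 * h, 4001)
        dens = np.exp(-0.5 * ((grid[:, None] - s) / h) ** 2).sum(axis=1)
        direct = int(np.sum((dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])))
        assert count_modes(s, h) == direct


class TestSizer:
    def test_grid_shape_and_exhaustive_labels(self, rng):
        s = rng.normal(size=300)
        m = sizer_map(s, grid_size=61, n_bandwidths=11)
        assert m.classes.shape == (11, 61)
        assert set(np.unique(m.classes)) <= set(SIZER_CLASSES)

    def test_symmetric_unimodal_pattern_at_large_bandwidth(self, rng):
        s = rng.normal(size=1000)
        m = sizer_map(s)
        row = m.classes[-1]  # largest bandwidth
        center = len(row) // 2
        assert (row[: center - 10] == "increasing").mean() > 0.7
        assert (row[center + 10 :] == "decreasing").mean() > 0.7

    def test_right_loaded_sample_mostly_increasing(self, rng):
        s = rng.beta(5, 1, size=1000)
        m = sizer_map(s)
        row = m.classes[-1]
        assert (row == "increasing").mean() > 0.5

    def test_requires_enough_data(self):
        with pytest.raises(ValueError):
            sizer_map(np.arange(5.0))
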