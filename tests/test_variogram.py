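"""Empirical semivariogram and Gaussian model fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenokrig import empirical_semivariogram, fit_variogram, gaussian_model_value
from phenokrig.variogram import EmpiricalVariogram, model_value

from conftest import make_dataset


def brute_force_semivariogram(dataset, n_lags, max_lag):
    """Exhaustive pair enumeration oracle, same binning contract."""
    pts = dataset.coords()
    z = dataset.values
    n = len(z)
    width = max_lag / n_lags
    per_bin_d = [[] for _ in range(n_lags)]
    per_bin_sq = [[] for _ in range(n_lags)]
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(pts[i], pts[j])
            # the guard tolerates one-ulp sqrt differences at the max-lag pair
            if d <= 0 or d > max_lag * (1 + 1e-12):
                continue
            k = min(math.ceil(d / width) - 1, n_lags - 1)
            per_bin_d[k].append(d)
            diff = float(z[i] - z[j])
            per_bin_sq[k].append(diff * diff)
    lags, gam, counts = [], [], []
    for ds_, sqs in zip(per_bin_d, per_bin_sq):
        if not ds_:
            continue
        lags.append(np.mean(np.array(ds_)))
        gam.append(np.mean(np.array(sqs)) / 2.0)
        counts.append(len(ds_))
    return np.array(lags), np.array(gam), np.array(counts)


class TestEmpiricalSemivariogram:
    def test_two_value_pair(self):
        ds = make_dataset([(0, 0), (100, 0), (0, 1)], [0.0, 2.0, 0.0])
        emp = empirical_semivariogram(ds, n_lags=1)
        # the (0,2) pairs dominate: gamma over all 3 pairs
        assert emp.pair_counts.sum() == 3

    def test_single_pair_gamma(self):
        ds = make_dataset([(0, 0), (100, 0), (200, 0)], [0.0, 1.0, 2.0])
        emp = empirical_semivariogram(ds, n_lags=2, max_lag=200.0)
        # bin 1: two pairs at d=100, (0-1)^2 and (1-2)^2 -> gamma 0.5
        # bin 2: one pair at d=200, (0-2)^2/2 = 2
        np.testing.assert_allclose(emp.gamma, [0.5, 2.0])
        np.testing.assert_allclose(emp.lags, [100.0, 200.0])

    def test_constant_field_zero_everywhere(self, random_dataset):
        ds = random_dataset(10, seed=1)
        ds.values[:] = 2.0
        emp = empirical_semivariogram(ds)
        assert np.all(emp.gamma == 0)

    def test_matches_brute_force_oracle(self, random_dataset):
        ds = random_dataset(10, seed=4)
        emp = empirical_semivariogram(ds, n_lags=6)
        lags, gam, counts = brute_force_semivariogram(ds, 6, emp.max_lag)
        # mean lags agree to distance-computation roundoff; bin contents exactly
        np.testing.assert_allclose(emp.lags, lags, rtol=1e-12)
        np.testing.assert_array_equal(emp.gamma, gam)
        np.testing.assert_array_equal(emp.pair_counts, counts)
        assert counts.sum() == 45  # all 10-choose-2 pairs retained

    def test_too_few_points(self, random_dataset):
        with pytest.raises(ValueError):
            empirical_semivariogram(random_dataset(2, seed=0))

    @given(st.floats(0.1, 3), st.floats(-1, 1), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_shift_invariance_and_scaling(self, a, b, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 5000, (8, 2))
        z = rng.uniform(1, 3, 8)
        base = empirical_semivariogram(make_dataset(coords, z))
        shifted = empirical_semivariogram(make_dataset(coords, np.clip(z + b, 0, 4)))
        # clip may bite; only assert when it did not
        if np.all((z + b >= 0) & (z + b <= 4)):
            np.testing.assert_allclose(shifted.gamma, base.gamma, rtol=1e-9, atol=1e-12)
        scaled_z = a * z
        if np.all(scaled_z <= 4):
            scaled = empirical_semivariogram(make_dataset(coords, scaled_z))
            np.testing.assert_allclose(
                scaled.gamma, a**2 * base.gamma, rtol=1e-9, atol=1e-12
            )


class TestGaussianModel:
    def test_zero_at_origin(self):
        assert gaussian_model_value(0.0, 0.1, 0.3, 1000.0) == 0.0

    def test_closed_form_at_range_param(self):
        C0, C, A0 = 0.05, 0.30, 2000.0
        expected = C0 + C * (1 - math.exp(-1))
        assert gaussian_model_value(A0, C0, C, A0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(C0 + 0.63212 * C, abs=1e-5)

    def test_asymptotic_sill(self):
        assert gaussian_model_value(20_000.0, 0.05, 0.30, 2000.0) == pytest.approx(
            0.35, abs=1e-9
        )

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            gaussian_model_value(-1.0, 0.0, 1.0, 100.0)

    @given(st.floats(0, 10_000), st.floats(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, h1, h2):
        C0, C, A0 = 0.05, 0.30, 2000.0
        lo, hi = sorted([h1, h2])
        g_lo, g_hi = (gaussian_model_value(h, C0, C, A0) for h in (lo, hi))
        if lo > 0:
            assert g_lo <= g_hi + 1e-15
        assert g_hi <= C0 + C + 1e-15

    @pytest.mark.parametrize("kind", ["spherical", "exponential"])
    def test_alternative_models_reach_sill(self, kind):
        assert model_value(1e7, kind, 0.1, 0.4, 1000.0) == pytest.approx(0.5, abs=1e-6)


class TestFitVariogram:
    def make_noiseless(self, C0=0.05, C=0.30, A0=2000.0, n=8):
        h = np.linspace(500, 8000, n)
        return EmpiricalVariogram(
            lags=h,
            gamma=gaussian_model_value(h, C0, C, A0),
            pair_counts=np.full(n, 10),
            max_lag=8000.0,
        )

    def test_noiseless_recovery(self):
        model = fit_variogram(self.make_noiseless())
        assert model.nugget == pytest.approx(0.05, abs=1e-6)
        assert model.structural_sill == pytest.approx(0.30, abs=1e-6)
        assert model.range_param == pytest.approx(2000.0, rel=1e-6)
        assert model.r2 == pytest.approx(1.0, abs=1e-9)
        assert model.rss == pytest.approx(0.0, abs=1e-12)
        assert model.effective_range == pytest.approx(math.sqrt(3) * model.range_param)

    def test_flat_bins_pure_nugget(self):
        emp = EmpiricalVariogram(
            lags=np.array([1000.0, 2000, 3000]),
            gamma=np.array([0.2, 0.2, 0.2]),
            pair_counts=np.array([5, 5, 5]),
            max_lag=3000.0,
        )
        model = fit_variogram(emp)
        assert model.pure_nugget
        assert model.nugget == pytest.approx(0.2)
        assert model.structural_sill == 0.0

    def test_noisy_fit_vs_grid_search_oracle(self):
        rng = np.random.default_rng(9)
        emp0 = self.make_noiseless()
        emp = EmpiricalVariogram(
            lags=emp0.lags,
            gamma=emp0.gamma * rng.uniform(0.9, 1.1, emp0.n_bins),
            pair_counts=emp0.pair_counts,
            max_lag=emp0.max_lag,
        )
        model = fit_variogram(emp)
        assert 0 < model.r2 < 1 and np.isfinite(model.rss) and model.rss > 0
        # independent coarse grid search over (C0, C, A0)
        best = np.inf
        for C0 in np.linspace(0, 0.2, 21):
            for C in np.linspace(0.1, 0.5, 41):
                for A0 in np.linspace(500, 4000, 36):
                    rss = np.sum(
                        (emp.gamma - gaussian_model_value(emp.lags, C0, C, A0)) ** 2
                    )
                    best = min(best, rss)
        assert model.rss <= best * 1.05

    def test_rss_never_exceeds_pure_nugget(self, random_dataset):
        for seed in range(5):
            ds = random_dataset(10, seed=seed)
            emp = empirical_semivariogram(ds)
            model = fit_variogram(emp)
            flat_rss = float(np.sum((emp.gamma - emp.gamma.mean()) ** 2))
            assert model.rss <= flat_rss + 1e-12

    def test_too_few_bins(self):
        emp = EmpiricalVariogram(
            lags=np.array([1000.0, 2000.0]),
            gamma=np.array([0.1, 0.2]),
            pair_counts=np.array([3, 3]),
            max_lag=2000.0,
        )
        with pytest.raises(ValueError, match="3 non-empty bins"):
            fit_variogram(emp)

    def test_pair_weighting_changes_objective(self):
        emp0 = self.make_noiseless()
        rng = np.random.default_rng(1)
        emp = EmpiricalVariogram(
            lags=emp0.lags,
            gamma=emp0.gamma * rng.uniform(0.8, 1.2, emp0.n_bins),
            pair_counts=np.array([1, 1, 1, 1, 50, 50, 50, 50]),
            max_lag=emp0.max_lag,
        )
        unweighted = fit_variogram(emp, weighting="none")
        weighted = fit_variogram(emp, weighting="pairs")
        assert np.isfinite(weighted.rss) and weighted.rss != unweighted.rss
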