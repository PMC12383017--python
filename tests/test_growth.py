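import numpy as np
import pytest

import dynapool as dp
from dynapool.errors import InsufficientDataError
from conftest import exact_catch

TRUE = dict(L_inf=591.2, k=0.098, t0=-0.225)


def _vbgf(t, L_inf, k, t0):
    return L_inf * (1 - np.exp(-k * (np.asarray(t, float) - t0)))


@pytest.fixture(scope="module")
def params():
    return dp.VBGFParams.from_points(**TRUE)


@pytest.fixture(scope="module")
def lw_fit():
    catch = exact_catch(b=2.94, a=2e-5, **TRUE, max_age=15)
    return dp.fit_power_law(catch)


class TestFitVBGF:
    def test_zero_noise_identifiability(self):
        ages = np.repeat(np.arange(16), 3)
        lengths = _vbgf(ages, **TRUE)
        fit = dp.fit_vbgf(ages, lengths)
        assert fit.L_inf.value == pytest.approx(TRUE["L_inf"], rel=1e-3)
        assert fit.k.value == pytest.approx(TRUE["k"], rel=1e-3)
        assert fit.t0.value == pytest.approx(TRUE["t0"], abs=1e-3)

    def test_single_age_insufficient(self):
        with pytest.raises(InsufficientDataError):
            dp.fit_vbgf([3] * 20, [200.0] * 20)

    def test_ci_coverage_with_gaussian_noise(self):
        hits = {"L_inf": 0, "k": 0, "t0": 0}
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            # ages from 1 so additive noise cannot push lengths negative
            ages = rng.integers(1, 16, 300)
            lengths = _vbgf(ages, **TRUE) + 15.0 * rng.standard_normal(300)
            fit = dp.fit_vbgf(ages, lengths)
            for name in hits:
                iv = getattr(fit, name if name != "L_inf" else "L_inf")
                if name == "k":
                    iv = fit.k
                if name == "t0":
                    iv = fit.t0
                if iv.lower <= TRUE[name] <= iv.upper:
                    hits[name] += 1
        for name, h in hits.items():
            assert h >= 90, f"{name}: {h}/{n_seeds} inside 95% CI"

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(2)
        ages = rng.integers(0, 14, 150)
        lengths = _vbgf(ages, **TRUE) + 10 * rng.standard_normal(150)
        f1 = dp.fit_vbgf(ages, lengths)
        f2 = dp.fit_vbgf(ages, lengths)
        assert (f1.L_inf.value, f1.k.value, f1.t0.value) == (
            f2.L_inf.value, f2.k.value, f2.t0.value)

    def test_age_shift_reparameterization(self):
        rng = np.random.default_rng(4)
        ages = rng.integers(0, 14, 200).astype(float)
        lengths = _vbgf(ages, **TRUE) + 5 * rng.standard_normal(200)
        base = dp.fit_vbgf(ages, lengths)
        shifted = dp.fit_vbgf(ages + 5.0, lengths)
        grid = np.linspace(0, 14, 30)
        np.testing.assert_allclose(
            dp.length_at_age(base, grid),
            dp.length_at_age(shifted, grid + 5.0),
            rtol=1e-5,
        )


class TestCurves:
    def test_root_and_asymptote(self, params, lw_fit):
        t0 = params.t0.value
        assert dp.length_at_age(params, t0) == pytest.approx(0.0, abs=1e-9)
        assert dp.weight_at_age(params, lw_fit, t0) == pytest.approx(0.0, abs=1e-9)
        far = t0 + 200 / params.k.value
        assert abs(dp.length_at_age(params, far) - params.L_inf.value) < 1e-6 * params.L_inf.value

    def test_weight_composes_allometry_with_length(self, params, lw_fit):
        rng = np.random.default_rng(0)
        ts = params.t0.value + rng.uniform(0.01, 40, 50)
        for t in ts:
            expected = lw_fit.a * dp.length_at_age(params, t) ** lw_fit.b
            assert dp.weight_at_age(params, lw_fit, t) == pytest.approx(expected, rel=1e-9)

    def test_length_monotone_and_bounded(self, params):
        grid = np.linspace(params.t0.value, 60, 500)
        lengths = dp.length_at_age(params, grid)
        assert np.all(np.diff(lengths) > 0)
        assert np.all(lengths <= params.L_inf.value)

    def test_closed_forms_match_finite_differences(self, params, lw_fit):
        grid = np.linspace(1.0, 30.0, 100)
        h = 1e-5
        dl, dw = dp.growth_rate(params, lw_fit, grid)
        num_dl = (dp.length_at_age(params, grid + h) - dp.length_at_age(params, grid - h)) / (2 * h)
        num_dw = (dp.weight_at_age(params, lw_fit, grid + h)
                  - dp.weight_at_age(params, lw_fit, grid - h)) / (2 * h)
        np.testing.assert_allclose(dl, num_dl, rtol=1e-6)
        np.testing.assert_allclose(dw, num_dw, rtol=1e-6)
        d2l, d2w = dp.growth_acceleration(params, lw_fit, grid)
        rate_hi = dp.growth_rate(params, lw_fit, grid + h)
        rate_lo = dp.growth_rate(params, lw_fit, grid - h)
        num_d2l = (rate_hi[0] - rate_lo[0]) / (2 * h)
        num_d2w = (rate_hi[1] - rate_lo[1]) / (2 * h)
        np.testing.assert_allclose(d2l, num_d2l, rtol=1e-5)
        np.testing.assert_allclose(d2w, num_d2w, rtol=1e-5)

    def test_rate_signs(self, params, lw_fit):
        grid = np.linspace(-5, 60, 200)
        dl, _ = dp.growth_rate(params, lw_fit, grid)
        d2l, _ = dp.growth_acceleration(params, lw_fit, grid)
        assert np.all(dl > 0) and np.all(d2l < 0)

    def test_rate_at_t0_is_linf_times_k(self, params, lw_fit):
        dl, _ = dp.growth_rate(params, lw_fit, params.t0.value)
        assert dl == pytest.approx(params.L_inf.value * params.k.value, rel=1e-12)


class TestDerivedAges:
    @pytest.mark.parametrize(
        "b,k,t0,expected",
        [
            (2.9375, 0.098, -0.225, 10.77),
            (2.9459, 0.118, -0.575, 8.58),
        ],
    )
    def test_inflection_age_reproduces_published_values(self, b, k, t0, expected):
        p = dp.VBGFParams.from_points(500.0, k, t0)
        assert round(dp.inflection_age(p, b), 2) == expected

    def test_inflection_age_analytic(self):
        p = dp.VBGFParams.from_points(100.0, 1.0, 0.0)
        assert dp.inflection_age(p, np.e) == pytest.approx(1.0)

    def test_no_inflection_below_one(self, params):
        with pytest.raises(ValueError):
            dp.inflection_age(params, 0.9)

    def test_weight_acceleration_zero_at_inflection(self, params, lw_fit):
        ti = dp.inflection_age(params, lw_fit.b)
        _, d2w = dp.growth_acceleration(params, lw_fit, ti)
        assert abs(d2w) < 1e-9

    def test_inflection_is_argmax_of_weight_rate(self, params, lw_fit):
        grid = np.arange(params.t0.value + 0.01, 40, 0.001)
        _, dw = dp.growth_rate(params, lw_fit, grid)
        ti_grid = grid[int(np.argmax(dw))]
        assert abs(dp.inflection_age(params, lw_fit.b) - ti_grid) <= 0.001

    def test_critical_age_analytic_case(self):
        p = dp.VBGFParams.from_points(100.0, 1.0, 0.0)
        assert dp.critical_age(p, 1.0, 1.0) == pytest.approx(np.log(2.0))

    def test_critical_age_reproduces_published_value(self):
        p = dp.VBGFParams.from_points(591.2325, 0.098, -0.225)
        assert dp.critical_age(p, 2.9375, 0.210) == pytest.approx(8.60, abs=0.03)

    def test_critical_age_is_cohort_biomass_argmax(self, params, lw_fit):
        M = 0.21
        tc = dp.critical_age(params, lw_fit.b, M)
        grid = np.arange(params.t0.value + 0.01, 60, 0.001)
        biomass = np.exp(-M * (grid - params.t0.value)) * dp.weight_at_age(params, lw_fit, grid)
        tc_grid = grid[int(np.argmax(biomass))]
        assert abs(tc - tc_grid) <= 0.001


class TestPerformanceIndex:
    @pytest.mark.parametrize(
        "k,L_inf,expected",
        [(0.098, 591.2325, 4.53), (0.122, 507.5575, 4.50), (1.0, 10.0, 2.0)],
    )
    def test_phi(self, k, L_inf, expected):
        p = dp.VBGFParams.from_points(L_inf, k, 0.0)
        assert round(dp.growth_performance_index(p), 2) == expected
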