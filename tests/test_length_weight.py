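import numpy as np
import pytest

import dynapool as dp
from dynapool.errors import InsufficientDataError, DegenerateInputError
from conftest import exact_catch


def _catch_from_arrays(lengths, weights, sexes=None, species="sp"):
    sexes = sexes or ["unknown"] * len(lengths)
    samples = [
        dp.FishSample(species, sx, 1, float(l), float(w))
        for l, w, sx in zip(lengths, weights, sexes)
    ]
    return dp.SampleSet(samples, species)


def _lognormal_catch(rng, n=200, a=2e-5, b=2.94, sd=0.1, sexes=None):
    lengths = rng.uniform(50, 450, n)
    weights = a * lengths**b * np.exp(sd * rng.standard_normal(n))
    return _catch_from_arrays(lengths, weights, sexes)


class TestFitPowerLaw:
    def test_exact_cubic_data_recovered(self):
        lengths = [100.0, 200.0, 400.0]
        catch = _catch_from_arrays(lengths, [1e-5 * l**3 for l in lengths])
        fit = dp.fit_power_law(catch)
        assert fit.b == pytest.approx(3.0, abs=1e-10)
        assert fit.a == pytest.approx(1e-5, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_insufficient(self):
        catch = _catch_from_arrays([100.0, 200.0], [10.0, 80.0])
        with pytest.raises(InsufficientDataError):
            dp.fit_power_law(catch)

    def test_zero_length_variance_degenerate(self):
        catch = _catch_from_arrays([100.0] * 5, [9.0, 10.0, 11.0, 10.5, 9.5])
        with pytest.raises(DegenerateInputError):
            dp.fit_power_law(catch)

    def test_ci_covers_truth_in_most_replicates(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = dp.fit_power_law(_lognormal_catch(rng))
            hits += fit.b_interval.lower <= 2.94 <= fit.b_interval.upper
        assert hits >= 90  # nominal 95% coverage

    def test_order_and_duplication_invariance(self, small_catch):
        fit = dp.fit_power_law(small_catch)
        shuffled = dp.SampleSet(list(reversed(small_catch.samples)), small_catch.species_id)
        doubled = dp.SampleSet(small_catch.samples * 2, small_catch.species_id)
        for other in (shuffled, doubled):
            fit2 = dp.fit_power_law(other)
            assert fit2.b == pytest.approx(fit.b, rel=1e-12)
            assert fit2.a == pytest.approx(fit.a, rel=1e-12)

    def test_length_rescaling_moves_only_a(self, small_catch):
        fit = dp.fit_power_law(small_catch)
        c = 0.1  # mm -> cm
        scaled = _catch_from_arrays(
            [s.body_length * c for s in small_catch],
            [s.body_weight for s in small_catch],
        )
        fit2 = dp.fit_power_law(scaled)
        assert fit2.b == pytest.approx(fit.b, rel=1e-9)
        assert fit2.a == pytest.approx(fit.a * c**-fit.b, rel=1e-6)


class TestIsometry:
    def test_b_exactly_three_gives_zero_statistic(self):
        catch = exact_catch(b=3.0)
        fit = dp.fit_power_law(catch)
        test = dp.isometry_t_test(fit, catch)
        assert test.t_statistic == pytest.approx(0.0, abs=1e-6)
        assert test.conclusion == "isometric"

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        catch = _lognormal_catch(rng, n=46)
        test = dp.isometry_t_test(dp.fit_power_law(catch), catch)
        assert test.df == 44

    def test_statistic_matches_wald_t(self):
        # the SD-ratio formula is algebraically |b - 3| / SE(b)
        rng = np.random.default_rng(3)
        catch = _lognormal_catch(rng)
        fit = dp.fit_power_law(catch)
        test = dp.isometry_t_test(fit, catch)
        assert test.t_statistic == pytest.approx(abs(fit.b - 3) / fit.b_se, rel=1e-9)

    def test_type_i_error_near_alpha(self):
        rejections = 0
        n_rep = 500
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            catch = _lognormal_catch(rng, n=100, b=3.0)
            test = dp.isometry_t_test(dp.fit_power_law(catch), catch)
            rejections += test.conclusion == "allometric"
        rate = rejections / n_rep
        mc_se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 2 * mc_se + 1e-12


class TestSexComparison:
    def test_identical_groups_show_no_difference(self):
        # same noisy point set for both sexes: interaction term exactly 0
        rng = np.random.default_rng(5)
        lengths = rng.uniform(50, 450, 50)
        weights = 2e-5 * lengths**2.94 * np.exp(0.05 * rng.standard_normal(50))
        catch = _catch_from_arrays(
            np.concatenate([lengths, lengths]),
            np.concatenate([weights, weights]),
            sexes=["female"] * 50 + ["male"] * 50,
        )
        res = dp.sex_slope_test(catch)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_detects_different_slopes(self):
        rng = np.random.default_rng(6)
        lf, lm = rng.uniform(50, 450, 100), rng.uniform(50, 450, 100)
        wf = 1e-3 * lf**2.5 * np.exp(0.02 * rng.standard_normal(100))
        wm = 1e-5 * lm**3.5 * np.exp(0.02 * rng.standard_normal(100))
        catch = _catch_from_arrays(
            np.concatenate([lf, lm]), np.concatenate([wf, wm]),
            sexes=["female"] * 100 + ["male"] * 100,
        )
        assert dp.sex_slope_test(catch).p_value < 0.001

    def test_small_group_rejected(self):
        catch = _catch_from_arrays(
            [100, 150, 200, 250], [10, 30, 80, 150],
            sexes=["female", "female", "female", "male"],
        )
        with pytest.raises(InsufficientDataError):
            dp.sex_slope_test(catch)

    def test_type_i_error_near_alpha(self):
        rejections = 0
        n_rep = 500
        for seed in range(n_rep):
            rng = np.random.default_rng(20_000 + seed)
            catch = _lognormal_catch(
                rng, n=120, sexes=["female"] * 60 + ["male"] * 60
            )
            rejections += dp.sex_slope_test(catch).p_value < 0.05
        rate = rejections / n_rep
        mc_se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 2 * mc_se + 1e-12
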