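import math

import numpy as np
import pytest
from scipy import integrate, stats

from lungscreen import (
    CountTable,
    TrialSimulator,
    binomial_excess_test,
    chi2_pvalue,
    default_truth,
    deviance,
    fit_model,
    generate_trial_counts,
    poisson_loglik,
)
from lungscreen.calibration import MODEL_SPECS, ModelSpec


def random_tables(n_tables, seed, max_count=50):
    """Pairs of (integer observed, positive expected) on the canonical layout."""
    rng = np.random.default_rng(seed)
    for _ in range(n_tables):
        obs = CountTable.zeros()
        exp = CountTable.zeros()
        obs.counts[:] = rng.integers(0, max_count, obs.counts.size).astype(float)
        exp.counts[:] = rng.uniform(0.1, max_count, exp.counts.size)
        yield obs, exp


def reference_deviance(obs_values, exp_values):
    """Straightforward per-cell evaluation of 2*[O ln(O/E) - (O - E)]."""
    total = 0.0
    for o, e in zip(obs_values, exp_values):
        term = -(o - e)
        if o > 0:
            term += o * math.log(o / e)
        total += 2.0 * term
    return total


class TestPoissonLoglik:
    def test_saturated_equality(self):
        obs = CountTable.from_dict({("intervention", "screen_detected", "II_minus"): 5,
                                    ("control", "clinically_diagnosed", "III_plus"): 9})
        assert poisson_loglik(obs, obs) == pytest.approx(
            sum(o * math.log(o) - o - math.lgamma(o + 1) for o in (5, 9))
        )

    def test_zero_observed_cell_formula(self):
        obs = CountTable.zeros()
        exp = CountTable.from_dict({("intervention", "screen_detected", "II_minus"): 2.0})
        assert poisson_loglik(obs, exp) == pytest.approx(-2.0)

    def test_saturated_model_maximizes_likelihood(self):
        for obs, exp in random_tables(25, seed=1):
            assert poisson_loglik(obs, exp) <= poisson_loglik(obs, obs) + 1e-12

    def test_zero_expected_with_observed_warns_and_is_minus_inf(self):
        obs = CountTable.from_dict({("intervention", "screen_detected", "II_minus"): 3})
        exp = CountTable.zeros()
        with pytest.warns(UserWarning):
            assert poisson_loglik(obs, exp) == -np.inf
        with pytest.warns(UserWarning):
            assert deviance(obs, exp) == np.inf

    def test_layout_mismatch_rejected(self):
        with pytest.raises(ValueError):
            poisson_loglik(CountTable.zeros(), CountTable.zeros(by_cell_type=True))


class TestDeviance:
    def test_saturated_deviance_is_exactly_zero(self):
        for obs, _ in random_tables(20, seed=2):
            assert deviance(obs, obs) == 0.0

    def test_matches_independent_evaluation(self):
        for obs, exp in random_tables(100, seed=3):
            ref = reference_deviance(obs.values(), exp.values())
            assert deviance(obs, exp) == pytest.approx(ref, abs=1e-10)

    def test_two_cell_worked_example(self):
        obs = CountTable.from_dict({
            ("intervention", "screen_detected", "II_minus"): 10,
            ("intervention", "clinically_diagnosed", "III_plus"): 20,
        })
        exp = CountTable.from_dict({
            ("intervention", "screen_detected", "II_minus"): 12.0,
            ("intervention", "clinically_diagnosed", "III_plus"): 18.0,
        })
        expected = 2 * (10 * math.log(10 / 12) + 20 * math.log(20 / 18))
        assert deviance(obs, exp) == pytest.approx(expected)
        assert expected == pytest.approx(0.568, abs=5e-4)

    def test_nonnegative_and_deviance_loglik_identity(self):
        """deviance = 2*(saturated loglik - model loglik), always >= 0."""
        for obs, exp in random_tables(50, seed=4):
            d = deviance(obs, exp)
            assert d >= 0.0
            assert d == pytest.approx(
                2 * (poisson_loglik(obs, obs) - poisson_loglik(obs, exp)), abs=1e-8
            )


class TestChi2Pvalue:
    @pytest.mark.parametrize(
        "dev,df,expected",
        [(2.14, 1, 0.14), (0.07, 1, 0.79), (5.04, 1, 0.02)],
    )
    def test_published_deviance_reductions_round_to_printed_p(self, dev, df, expected):
        assert round(chi2_pvalue(dev, df), 2) == expected

    def test_zero_reduction_gives_p_one(self):
        for df in (1, 2, 5):
            assert chi2_pvalue(0.0, df) == 1.0

    def test_strictly_decreasing_in_reduction(self):
        ps = [chi2_pvalue(x, 1) for x in np.linspace(0.01, 10, 50)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_agrees_with_numerical_integration(self):
        for dev, df in [(2.14, 1), (5.04, 1), (3.3, 2), (7.7, 4)]:
            tail, _ = integrate.quad(stats.chi2(df).pdf, dev, np.inf)
            assert chi2_pvalue(dev, df) == pytest.approx(tail, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            chi2_pvalue(-0.1, 1)
        with pytest.raises(ValueError):
            chi2_pvalue(1.0, 0)


class TestBinomialExcess:
    def test_observed_at_expectation_is_near_half(self):
        assert 0.45 < binomial_excess_test(500, 500.0, 10_000) < 0.55

    def test_all_successes_closed_form(self):
        n, expected = 5, 2.0
        assert binomial_excess_test(5, expected, n) == pytest.approx((expected / n) ** n)

    def test_matches_scipy_binomtest(self):
        ours = binomial_excess_test(206, 187.8, 4618)
        ref = stats.binomtest(206, 4618, 187.8 / 4618, alternative="greater").pvalue
        assert ours == pytest.approx(ref)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_excess_test(11, 5.0, 10)
        with pytest.raises(ValueError):
            binomial_excess_test(5, 12.0, 10)
        with pytest.raises(ValueError):
            binomial_excess_test(5, 0.0, 10)


@pytest.fixture(scope="module")
def small_sim():
    truth = default_truth(seed=21, n_intervention=2500, n_control=2500)
    sim = TrialSimulator(truth.trial, truth.nh, truth.test, truth.life_table,
                         oversample=10, seed=21)
    obs = generate_trial_counts(truth, seed=22)
    return sim, obs


class TestFitModel:
    def test_simple_model_is_a_single_evaluation(self, small_sim):
        sim, obs = small_sim
        fit = fit_model(MODEL_SPECS["Simple"], obs, sim)
        assert fit.n_evals == 1
        assert fit.fitted_values == {}
        assert fit.deviance >= 0.0
        assert fit.deviance == pytest.approx(deviance(obs, sim.expected()))

    def test_non_integer_observed_rejected(self, small_sim):
        sim, _ = small_sim
        bad = CountTable.from_dict({("intervention", "screen_detected", "II_minus"): 1.5})
        with pytest.raises(ValueError):
            fit_model(MODEL_SPECS["Simple"], bad, sim)

    def test_fit_is_deterministic_given_seed(self, small_sim):
        sim, obs = small_sim
        a = fit_model(MODEL_SPECS["RiskDifference"], obs, sim)
        b = fit_model(MODEL_SPECS["RiskDifference"], obs, sim)
        assert a.fitted_values == b.fitted_values
        assert a.deviance == b.deviance

    def test_nested_extension_never_fits_worse(self, small_sim):
        """SensitivityError nests SystematicError; with shared draws its
        deviance cannot exceed the smaller model's by more than tolerance."""
        sim, obs = small_sim
        d_sys = fit_model(MODEL_SPECS["SystematicError"], obs, sim,
                          maxfev=80, n_restarts=2).deviance
        d_both = fit_model(MODEL_SPECS["SensitivityError"], obs, sim,
                           maxfev=160, n_restarts=2).deviance
        assert d_both <= d_sys + 0.5

    def test_fitted_values_respect_bounds(self, small_sim):
        sim, obs = small_sim
        fit = fit_model(MODEL_SPECS["Sensitivity"], obs, sim, maxfev=60, n_restarts=2)
        for name, v in fit.fitted_values.items():
            lo, hi = MODEL_SPECS["Sensitivity"].bounds[name]
            assert lo <= v <= hi


class TestModelSpecDefinitions:
    def test_each_named_model_frees_its_hypothesis_parameters(self):
        frees = {name: set(spec.free_params) for name, spec in MODEL_SPECS.items()}
        assert frees["Simple"] == set()
        assert frees["Sensitivity"] == {"sens_II", "sens_III"}
        assert frees["SystematicError"] == {"syserr_II", "syserr_III"}
        assert frees["SensitivityError"] == {
            "sens_II", "sens_III", "syserr_II", "syserr_III"
        }
        assert frees["Overdiagnosis"] == {"indolent_fraction"}
        assert frees["RiskDifference"] == {"risk_factor"}

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("X", ("nope",), {"nope": (0, 1)}, {"nope": 0.5})
        with pytest.raises(ValueError):
            ModelSpec("X", ("risk_factor",), {"risk_factor": (1.0, 0.5)},
                      {"risk_factor": 0.7})


class TestMultinomialFamily:
    def test_conditioning_cancels_arm_totals(self):
        """With per-arm totals matched, only allocation misfit remains."""
        obs = CountTable.from_dict({
            ("intervention", "screen_detected", "II_minus"): 60,
            ("intervention", "clinically_diagnosed", "III_plus"): 140,
            ("control", "clinically_diagnosed", "III_plus"): 100,
        })
        # same allocation, half the scale: multinomial deviance is zero
        exp = CountTable(obs.counts * 0.5)
        assert deviance(obs, exp, family="multinomial") == pytest.approx(0.0)
        assert deviance(obs, exp) > 0  # the Poisson family penalizes the scale

    def test_unknown_family_rejected(self):
        obs = CountTable.zeros()
        with pytest.raises(ValueError):
            deviance(obs, obs, family="negbin")


class TestSingleSensitivityRecovery:
    def test_one_freed_sensitivity_is_recovered(self):
        """A single freed sens_II recovers a truth of 0.8 on average."""
        from lungscreen import TestCharacteristics

        spec = ModelSpec("SensII", ("sens_II",), {"sens_II": (0.5, 1.0)},
                         {"sens_II": 0.9})
        null = default_truth(seed=61, n_intervention=4618, n_control=4593)
        sim = TrialSimulator(null.trial, null.nh, null.test, null.life_table,
                             oversample=15, seed=62)
        estimates = []
        for r in range(6):
            truth = default_truth(seed=63 + r, test=TestCharacteristics(sens_II=0.8))
            obs = generate_trial_counts(truth, seed=63 + r)
            fit = fit_model(spec, obs, sim)
            estimates.append(fit.fitted_values["sens_II"])
        assert abs(np.mean(estimates) - 0.8) < 0.1
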