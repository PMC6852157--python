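import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from benthic_encounters import (FittedResponse, HollingParams, aicc,
                                bootstrap_mean_q,
                                capture_rate_at_half_saturation,
                                classify_proportional_trend, fit_all_variants,
                                fit_model, holling_rate, neg_log_likelihood,
                                rogers_eaten, select_response)
from benthic_encounters.synthetic_data import generate_trials, geometric_levels
from benthic_encounters.trials import TrialSet


def rogers_fixed_point(N0, T, b, h, q, damping=0.5, tol=1e-12):
    """Damped fixed-point iteration x <- N0(1 - exp(c(hx - T))): an
    independent oracle for the depletion solver."""
    c = b * N0 ** q
    x = 0.0
    for _ in range(100000):
        xn = N0 * (1 - math.exp(min(c * (h * x - T), 700)))
        if abs(xn - x) < tol:
            return xn
        x = (1 - damping) * x + damping * xn
    raise RuntimeError("oracle did not converge")


class TestHollingRate:
    def test_zero_density(self):
        assert holling_rate(0.0, HollingParams(b=1, h=1)) == 0.0

    def test_half_saturation_identity(self):
        b, h = 0.4, 2.5
        rate = holling_rate(1 / (b * h), HollingParams(b=b, h=h))
        assert rate == pytest.approx(1 / (2 * h))

    def test_direct_substitution_type3(self):
        rate = holling_rate(1.0, HollingParams(b=2, h=0.5, q=1))
        assert rate == pytest.approx(1.0)

    @given(st.floats(0, 100), st.floats(0.01, 100))
    def test_monotone_and_saturating(self, n1, n2):
        params = HollingParams(b=0.3, h=0.7, q=0.5)
        lo, hi = sorted((n1, n2))
        assert holling_rate(lo, params) <= holling_rate(hi, params) + 1e-12
        assert holling_rate(hi, params) <= 1 / params.h


class TestRogersEaten:
    def test_no_capture(self):
        assert rogers_eaten(10, 1.0, HollingParams(b=0.0)) == 0.0

    def test_h_zero_reduces_to_exponential_depletion(self):
        ne = rogers_eaten(10, math.log(2), HollingParams(b=1.0))
        assert ne == pytest.approx(5.0, rel=1e-12)

    def test_fixed_point_oracle(self):
        expected = rogers_fixed_point(20, 1.0, b=0.05, h=0.2, q=0)
        lw = rogers_eaten(20, 1.0, HollingParams(b=0.05, h=0.2))
        assert lw == pytest.approx(expected, rel=1e-8)

    def test_lambertw_matches_bracketed_root(self):
        params = HollingParams(b=0.05, h=0.2)
        lw = rogers_eaten(20, 1.0, params, method="lambertw")
        bq = rogers_eaten(20, 1.0, params, method="brentq")
        assert lw == pytest.approx(bq, rel=1e-8)

    def test_classic_rogers_form_at_q_zero(self):
        # the q=0 depletion coefficient is plain b, independent of N0
        params = HollingParams(b=0.1, h=0.5)
        direct = rogers_fixed_point(30, 2.0, b=0.1, h=0.5, q=0)
        assert rogers_eaten(30, 2.0, params) == pytest.approx(direct, rel=1e-9)

    def test_printed_exponent_convention_differs_for_q_positive(self):
        params = HollingParams(b=0.01, h=0.1, q=1)
        a = rogers_eaten(50, 1.0, params, exponent_convention="q")
        b = rogers_eaten(50, 1.0, params, exponent_convention="q_plus_1")
        assert b > a  # steeper density dependence as printed

    @given(st.integers(1, 500), st.floats(0.01, 5.0), st.floats(1e-3, 1.0),
           st.floats(0.0, 2.0), st.sampled_from([0.0, 0.5, 1.0, 2.0]))
    def test_bounds_and_monotonicity(self, n0, T, b, h, q):
        params = HollingParams(b=b, h=h, q=q)
        ne = rogers_eaten(n0, T, params)
        assert 0.0 <= ne <= n0
        assert ne <= holling_rate(float(n0), params) * T + 1e-9
        assert ne <= rogers_eaten(n0 + 1, T, params) + 1e-9
        assert ne <= rogers_eaten(n0, T * 1.5, params) + 1e-9


class TestNegLogLikelihood:
    def _single(self, n0, eaten, **kw):
        return TrialSet(pair_id="x", N0=[n0], eaten=[eaten], T=kw.pop("T", 1.0))

    def test_certain_zero(self):
        t = self._single(1, 0)
        assert neg_log_likelihood(HollingParams(b=0.0), t) == pytest.approx(
            0.0, abs=1e-6)

    def test_half_probability_binomial(self):
        # b = ln2/T makes the depletion probability exactly 1/2
        t = TrialSet(pair_id="x", N0=[2], eaten=[1], T=1.0)
        nll = neg_log_likelihood(HollingParams(b=math.log(2)), t)
        assert nll == pytest.approx(-math.log(0.5), rel=1e-9)

    def test_term_by_term_oracle(self):
        params = HollingParams(b=0.3, h=0.15, q=0.0)
        t = TrialSet(pair_id="x", N0=[2, 4, 8, 16], eaten=[1, 2, 3, 5], T=1.0)
        expected = 0.0
        for n0, ne in zip(t.N0, t.eaten):
            p = rogers_eaten(int(n0), 1.0, params) / n0
            expected -= math.log(math.comb(int(n0), int(ne))
                                 * p ** ne * (1 - p) ** (n0 - ne))
        assert neg_log_likelihood(params, t) == pytest.approx(expected,
                                                              rel=1e-9)


class TestFitModel:
    def test_recovers_type2_parameters(self, type2_trials):
        true, trials = type2_trials
        fit = fit_model(trials, "II", compute_se=False)
        assert fit.converged
        assert fit.params.b == pytest.approx(true.b, rel=0.25)
        assert fit.params.h == pytest.approx(true.h, rel=0.35)

    def test_variant_I_matches_linear_generator(self):
        # proportionally constant consumption: pure exponential depletion
        true = HollingParams(b=0.2, h=0.0, q=0.0)
        trials = generate_trials(true, geometric_levels(5), 30, 1.0, 5)
        fit = fit_model(trials, "I", compute_se=False)
        assert fit.params.b == pytest.approx(0.2, rel=0.15)

    def test_general_variant_finds_sigmoidal_exponent(self, type3_trials):
        true, trials = type3_trials
        fit = fit_model(trials, "general", compute_se=False)
        assert fit.params.q == pytest.approx(1.0, abs=0.5)

    def test_all_zero_counts_yield_flagged_null_fit(self):
        trials = TrialSet(pair_id="z", N0=[2, 4, 8, 16] * 3,
                          eaten=[0] * 12, T=1.0)
        fit = fit_model(trials, "II")
        assert fit.flag == "all_zero_null_fit"
        assert fit.params.b == 0.0

    def test_too_few_replicates_rejected(self):
        trials = TrialSet(pair_id="s", N0=[2, 4], eaten=[1, 1], T=1.0)
        with pytest.raises(ValueError):
            fit_model(trials, "general")

    def test_wald_errors_cover_truth(self, type2_trials):
        true, trials = type2_trials
        fit = fit_model(trials, "II")
        assert abs(fit.params.b - true.b) < 4 * fit.param_se["b"]
        assert abs(fit.params.h - true.h) < 4 * fit.param_se["h"]


class TestSelection:
    @staticmethod
    def _dummy(variant, aicc_val, k=2, q=0.0):
        return FittedResponse(params=HollingParams(b=1, h=1, q=q),
                              variant=variant, loglik=0.0, k=k, n=50,
                              AICc=aicc_val)

    def test_clear_winner_selected_outright(self, type2_trials):
        _, trials = type2_trials
        fits = {"I": self._dummy("I", 100, k=1), "II": self._dummy("II", 90),
                "III": self._dummy("III", 95),
                "general": self._dummy("general", 94, k=3)}
        assert select_response(fits, trials).variant == "II"

    def test_aicc_arithmetic(self):
        assert aicc(-10, 2, 20) == pytest.approx(24 + 12 / 17)
        assert math.isinf(aicc(-10, 3, 4))

    def test_competitive_type2_resolved_by_diagnostic(self, type2_trials):
        true, trials = type2_trials
        sel = select_response(fit_all_variants(trials, compute_se=False),
                              trials)
        assert sel.variant in ("II", "general")
        if sel.variant == "general":
            assert sel.params.q < 0.5


class TestProportionalTrend:
    def test_constant_proportions_flat(self):
        n0 = np.repeat([4, 8, 16, 32, 64], 4)
        trials = TrialSet(pair_id="f", N0=n0, eaten=n0 // 2, T=1.0)
        assert classify_proportional_trend(trials) == "flat"

    def test_decreasing_proportions(self):
        n0 = np.repeat([4, 8, 16, 32, 64], 4)
        eaten = (n0 * (0.8 - 0.1 * np.log2(n0 / 4))).astype(int)
        trials = TrialSet(pair_id="d", N0=n0, eaten=eaten, T=1.0)
        assert classify_proportional_trend(trials) == "decreasing"

    def test_sigmoidal_generator_makes_hump(self, type3_trials):
        _, trials = type3_trials
        assert classify_proportional_trend(trials) == "hump"

    def test_single_level_rejected(self):
        trials = TrialSet(pair_id="s", N0=[8] * 6, eaten=[2] * 6, T=1.0)
        with pytest.raises(ValueError):
            classify_proportional_trend(trials)


class TestDerivedRates:
    def test_type2_reduces_to_b(self):
        assert capture_rate_at_half_saturation(
            HollingParams(b=0.3, h=1.0)) == pytest.approx(0.3)

    def test_type3_closed_form(self):
        # N_half = (b h)^(-1/2) = 0.5, so b N_half = 2
        rate = capture_rate_at_half_saturation(HollingParams(b=4, h=1, q=1))
        assert rate == pytest.approx(2.0)

    def test_derivative_mode_cross_check(self):
        params = HollingParams(b=0.8, h=0.6, q=1.3)
        n_half = (params.b * params.h) ** (-1 / (params.q + 1))
        eps = 1e-6
        numeric = (holling_rate(n_half + eps, params)
                   - holling_rate(n_half - eps, params)) / (2 * eps)
        analytic = capture_rate_at_half_saturation(params, mode="derivative")
        assert analytic == pytest.approx(numeric, rel=1e-5)

    def test_unsaturating_response_warns(self):
        with pytest.warns(UserWarning):
            rate = capture_rate_at_half_saturation(HollingParams(b=0.5, h=0.0))
        assert rate == 0.5


class TestBootstrapMeanQ:
    def test_degenerate_group_has_zero_width(self):
        out = bootstrap_mean_q({"g": np.full(10, 0.7)}, n_boot=100, seed=1)
        assert out.loc[0, "ci_lo"] == out.loc[0, "ci_hi"] == 0.7

    def test_two_point_group_centres_on_half(self):
        out = bootstrap_mean_q({"g": np.array([0.0, 1.0])},
                               n_boot=4000, seed=2)
        assert out.loc[0, "mean_q"] == 0.5
        assert out.loc[0, "ci_lo"] <= 0.5 <= out.loc[0, "ci_hi"]

    def test_deterministic_under_seed(self):
        groups = {"a": np.array([0.0, 0.3, 1.0]), "b": np.array([0.5, 0.9])}
        first = bootstrap_mean_q(groups, n_boot=500, seed=9)
        second = bootstrap_mean_q(groups, n_boot=500, seed=9)
        assert first.equals(second)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean_q({"g": np.array([])}, n_boot=10, seed=0)
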