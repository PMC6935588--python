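"""Cline curve, likelihoods, AICc selection, 2-LLU intervals and MCMC fitting."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hzmove.core import ValidationError
from hzmove.geocline import (
    ClineModel,
    FreqClineData,
    ModelSpec,
    TraitClineData,
    aicc,
    centre_shift_km,
    cline_value,
    fit_mcmc,
    fit_null_freq,
    fit_null_trait,
    frequency_model_specs,
    loglik_freq,
    loglik_trait,
    select_model,
    trait_model_specs,
    two_llu_interval,
    width_difference_km,
)
from hzmove.synthdata import frequency_cline_dataset


class TestClineValue:
    def test_centre_of_unit_cline_is_half(self):
        m = ClineModel(centre=1000.0, width=300.0)
        assert cline_value(1000.0, m) == pytest.approx(0.5)

    def test_half_width_displacement(self):
        m = ClineModel(centre=1000.0, width=300.0)
        assert cline_value(1150.0, m) == pytest.approx((1 + np.tanh(1.0)) / 2)
        assert cline_value(1150.0, m) == pytest.approx(0.880797, abs=1e-6)

    def test_tail_joins_core_continuously(self):
        for tail in ("left", "right", "mirror", "independent"):
            m = ClineModel(
                1000.0, 200.0, tail_mode=tail, delta_l=80.0, tau_l=1.0, delta_r=80.0, tau_r=1.0
            )
            for xj in (920.0, 1080.0):
                lo, hi = cline_value(xj - 1e-6, m), cline_value(xj + 1e-6, m)
                assert lo == pytest.approx(hi, abs=1e-5)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValidationError):
            ClineModel(0.0, -5.0)

    @given(
        tail=st.sampled_from(("none", "left", "right", "mirror", "independent")),
        delta=st.floats(0.0, 500.0),
        tau=st.floats(0.0, 1.0),
        width=st.floats(1.0, 2000.0),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_nondecreasing_for_all_tail_modes(self, tail, delta, tau, width):
        m = ClineModel(
            1000.0, width, tail_mode=tail, delta_l=delta, tau_l=tau, delta_r=delta, tau_r=tau
        )
        x = np.linspace(-500.0, 2500.0, 400)
        y = cline_value(x, m)
        assert np.all(np.diff(y) >= -1e-12)
        assert y.min() >= -1e-12 and y.max() <= 1 + 1e-12


class TestLikelihoods:
    def test_binomial_closed_form(self):
        m = ClineModel(0.0, 1.0)  # value 0.5 at x=0
        data = FreqClineData(np.array([0.0]), np.array([1]), np.array([2]))
        # ln C(2,1) + ln(0.5) + ln(0.5) = ln(0.5)
        assert loglik_freq(m, data) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_epsilon_clipped_likelihood_is_finite(self):
        m = ClineModel(1e6, 1.0)  # predicted frequency ~ 0 on the transect
        data = FreqClineData(np.array([0.0, 10.0]), np.array([3, 2]), np.array([10, 10]))
        ll = loglik_freq(m, data)
        assert np.isfinite(ll) and ll < -20

    def test_trait_residual_of_one_standard_error(self):
        m = ClineModel(0.0, 1.0, pmin=5.0, pmax=5.0)  # flat at 5
        se = 2.0 / np.sqrt(4.0)
        data = TraitClineData(np.array([100.0]), np.array([5.0 + se]), np.array([2.0]), np.array([4]))
        base = TraitClineData(np.array([100.0]), np.array([5.0]), np.array([2.0]), np.array([4]))
        assert loglik_trait(m, data) - loglik_trait(m, base) == pytest.approx(-0.5)

    def test_larger_samples_tighten_the_trait_likelihood(self):
        # a misfit of one within-population SD is penalised more as n grows
        m = ClineModel(0.0, 1.0, pmin=5.0, pmax=5.0)
        resid = 2.0
        lls = []
        for n in (4, 16):
            d = TraitClineData(np.array([0.0]), np.array([5.0 + resid]), np.array([2.0]), np.array([n]))
            lls.append(loglik_trait(m, d))
        assert lls[1] < lls[0]

    def test_agrees_with_bruteforce_pmf_sums(self, rng):
        from scipy import stats

        m = ClineModel(800.0, 350.0, pmin=0.1, pmax=0.9, tail_mode="mirror", delta_l=100.0, tau_l=0.5, delta_r=100.0, tau_r=0.5)
        x = rng.uniform(0, 2000, 12)
        total = rng.integers(5, 30, 12)
        count = rng.binomial(total, 0.4)
        data = FreqClineData(x, count, total)
        p = np.clip(cline_value(x, m), 1e-9, 1 - 1e-9)
        brute = sum(stats.binom.logpmf(k, n, pi) for k, n, pi in zip(count, total, p))
        assert loglik_freq(m, data) == pytest.approx(brute, abs=1e-10)

        mean = rng.normal(0.5, 0.1, 12)
        sd = rng.uniform(0.05, 0.2, 12)
        nn = rng.integers(2, 9, 12)
        tdata = TraitClineData(x, mean, sd, nn)
        mu = cline_value(x, m)
        bruteg = sum(
            stats.norm.logpdf(mi, mui, si / np.sqrt(ni))
            for mi, mui, si, ni in zip(mean, mu, sd, nn)
        )
        assert loglik_trait(m, tdata) == pytest.approx(bruteg, abs=1e-10)


class TestAICc:
    def test_worked_example(self):
        assert aicc(-10.0, 2, 10) == pytest.approx(20 + 4 + 12 / 7)
        assert aicc(-10.0, 2, 10) == pytest.approx(25.714, abs=1e-3)

    def test_zero_parameters(self):
        assert aicc(-7.5, 0, 20) == pytest.approx(15.0)

    def test_parsimony_wins_ties(self):
        assert aicc(-10.0, 1, 30) < aicc(-10.0, 2, 30)

    def test_undefined_when_sample_too_small(self):
        with pytest.warns(UserWarning):
            assert np.isinf(aicc(-10.0, 5, 6))


class TestTwoLLU:
    def test_quadratic_profile(self):
        theta = np.linspace(0.0, 10.0, 501)
        lnl = -((theta - 5.0) ** 2) / 2.0
        iv = two_llu_interval(theta, lnl, 5.0, 0.0)
        assert iv.low == pytest.approx(3.0, abs=0.02)
        assert iv.high == pytest.approx(7.0, abs=0.02)
        assert iv.contains(5.0)

    def test_flat_profile_flagged_unbounded(self):
        theta = np.linspace(0, 10, 50)
        iv = two_llu_interval(theta, np.zeros(50), 5.0, 0.0)
        assert not iv.lower_bounded and not iv.upper_bounded

    def test_mle_at_edge_gives_one_sided_interval(self):
        theta = np.linspace(0, 10, 50)
        lnl = -theta
        iv = two_llu_interval(theta, lnl, 0.0, 0.0)
        assert not iv.lower_bounded and iv.upper_bounded
        assert iv.high == pytest.approx(2.0, abs=0.25)


class TestModelSelection:
    def test_single_fit_against_null_ties_go_to_null(self):
        data = FreqClineData(np.linspace(0, 100, 10), np.full(10, 5), np.full(10, 10))
        null = fit_null_freq(data)
        from hzmove.geocline import ClineFit

        rival = ClineFit(ModelSpec("freq", "none", "fixed01"), None, {}, null.lnl, 2, 10, aicc(null.lnl, 2, 10))
        best = select_model([rival, null])
        assert best.is_null

    def test_family_sizes(self):
        assert len(frequency_model_specs()) == 15
        assert len(trait_model_specs()) == 5

    def test_null_trait_weighted_mean(self):
        data = TraitClineData(
            np.array([0.0, 10.0]), np.array([1.0, 3.0]), np.array([1.0, 1.0]), np.array([4, 1])
        )
        fit = fit_null_trait(data)
        # precision weights n/sd^2 = 4 and 1
        assert fit.params["mean"] == pytest.approx((4 * 1.0 + 1 * 3.0) / 5)


class TestFitMCMC:
    def test_same_seed_reproduces_the_fit(self):
        x, k, n = frequency_cline_dataset(n_pops=15, seed=11)
        data = FreqClineData(x, k, n)
        spec = ModelSpec("freq", "none", "fixed01")
        f1 = fit_mcmc(spec, data, chain_len=1500, burnin=400, n_chains=2, seed=9)
        f2 = fit_mcmc(spec, data, chain_len=1500, burnin=400, n_chains=2, seed=9)
        assert f1.model.centre == f2.model.centre
        assert f1.lnl == f2.lnl

    def test_recovers_a_clean_cline(self):
        x, k, n = frequency_cline_dataset(n_pops=30, alleles_per_pop=40, centre=1500, width=120, seed=3)
        data = FreqClineData(x, k, n)
        fit = fit_mcmc(ModelSpec("freq", "none", "fixed01"), data, chain_len=6000, burnin=1500, n_chains=3, seed=1)
        assert fit.intervals["centre"].contains(1500.0)
        assert 60 < fit.model.width < 250

    def test_interval_shrinks_with_information(self):
        widths = []
        for n_alleles in (10, 100, 1000):
            x, k, n = frequency_cline_dataset(n_pops=20, alleles_per_pop=n_alleles, seed=5)
            fit = fit_mcmc(
                ModelSpec("freq", "none", "fixed01"),
                FreqClineData(x, k, n),
                chain_len=4000,
                burnin=1000,
                n_chains=2,
                seed=2,
            )
            widths.append(fit.intervals["centre"].width)
        assert widths[2] < widths[1] < widths[0]

    def test_needs_at_least_four_populations(self):
        data = FreqClineData(np.array([0.0, 50.0, 100.0]), np.array([1, 2, 3]), np.array([4, 4, 4]))
        with pytest.raises(ValidationError):
            fit_mcmc(ModelSpec("freq", "none", "fixed01"), data)


class TestSummaryArithmetic:
    def test_centre_shift_is_signed_displacement_from_trait_mean(self):
        assert centre_shift_km(1523.0, [1054.0, 1100.0]) == pytest.approx(446.0)

    def test_width_difference_signed(self):
        assert width_difference_km(898.0, 845.0) == pytest.approx(53.0)
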