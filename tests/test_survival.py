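"""Survival families: parameterizations, MLE fitting, model selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import LogLogisticFitter, LogNormalFitter, WeibullFitter
from scipy import stats

from psmcea.survival import (FitError, SurvivalSpec, default_rp_knots, fit_mle,
                             restricted_mean, rp_basis, select_best,
                             survival_at)


def spec(family, **params):
    return SurvivalSpec(family, params)


SPECS = [
    spec("exponential", rate=0.08),
    spec("weibull", shape=1.3, scale=12.0),
    spec("log_logistic", shape=1.6417, scale=8.4452),
    spec("log_normal", meanlog=3.6682, sdlog=1.6679),
    spec("gompertz", shape=-0.05, rate=0.09),
    spec("gompertz", shape=0.04, rate=0.02),
    spec("gen_gamma", mu=2.5, sigma=0.9, q=0.7),
    spec("gen_gamma", mu=2.5, sigma=0.9, q=-0.6),
    SurvivalSpec("royston_parmar", knots=(0.0, 1.5, 2.5, 3.5),
                 gamma=(-2.5, 1.1, 0.05, -0.02)),
    SurvivalSpec("mixture_cure", {"pi": 0.3},
                 base=spec("weibull", shape=1.2, scale=10.0)),
    SurvivalSpec("nonmixture_cure", {"pi": 0.3},
                 base=spec("weibull", shape=1.2, scale=10.0)),
]


class TestSurvivalFunctions:
    @pytest.mark.parametrize("s", SPECS, ids=lambda s: s.family)
    def test_valid_survival_curve(self, s):
        """S(0)=1, non-increasing, bounded in [0,1] out to long horizons."""
        t = np.linspace(0.0, 600.0, 2001)
        surv = s.survival(t)
        assert surv[0] == pytest.approx(1.0)
        assert np.all(surv <= 1.0) and np.all(surv >= 0.0)
        assert np.all(np.diff(surv) <= 1e-12)

    def test_log_logistic_median_at_scale(self):
        s = spec("log_logistic", shape=1.6417, scale=8.4452)
        assert survival_at(s, 8.4452) == pytest.approx(0.5)

    def test_log_normal_matches_trial_12_month_os(self):
        """Published NI+CA OS parameters reproduce the trial's 85.7% 12-month
        OS probability (normal-CDF oracle)."""
        s = spec("log_normal", meanlog=4.1874, sdlog=1.5868)
        oracle = stats.norm.sf((math.log(12.0) - 4.1874) / 1.5868)
        assert survival_at(s, 12.0) == pytest.approx(oracle, abs=1e-12)
        assert survival_at(s, 12.0) == pytest.approx(0.857, abs=0.002)

    def test_mixture_cure_plateau(self):
        s = SurvivalSpec("mixture_cure", {"pi": 0.3},
                         base=spec("exponential", rate=1.0))
        assert survival_at(s, 1e4) == pytest.approx(0.3, abs=1e-12)

    def test_nonmixture_cure_plateau(self):
        s = SurvivalSpec("nonmixture_cure", {"pi": 0.3},
                         base=spec("exponential", rate=1.0))
        assert survival_at(s, 1e4) == pytest.approx(0.3, rel=1e-9)

    def test_mixture_cure_pi_zero_reduces_to_base(self):
        base = spec("weibull", shape=1.4, scale=9.0)
        cure = SurvivalSpec("mixture_cure", {"pi": 0.0}, base=base)
        t = np.linspace(0.0, 200.0, 500)
        assert np.max(np.abs(cure.survival(t) - base.survival(t))) < 1e-12

    def test_nonmixture_cure_pi_one_is_no_event(self):
        cure = SurvivalSpec("nonmixture_cure", {"pi": 1.0},
                            base=spec("exponential", rate=0.5))
        assert survival_at(cure, 500.0) == pytest.approx(1.0)

    def test_gompertz_negative_shape_plateaus(self):
        s = spec("gompertz", shape=-0.1, rate=0.05)
        plateau = math.exp(-0.05 / 0.1)   # closed-form asymptote exp(b/a)
        assert survival_at(s, 1e4) == pytest.approx(plateau, rel=1e-9)

    def test_gen_gamma_q_zero_is_log_normal(self):
        gg = spec("gen_gamma", mu=3.0, sigma=1.2, q=0.0)
        ln = spec("log_normal", meanlog=3.0, sdlog=1.2)
        t = np.linspace(0.1, 300.0, 100)
        np.testing.assert_allclose(gg.survival(t), ln.survival(t), atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            SPECS[0].survival(-1.0)

    def test_malformed_parameters_rejected(self):
        with pytest.raises(ValueError):
            spec("weibull", shape=-1.0, scale=2.0)
        with pytest.raises(ValueError):
            spec("log_normal", meanlog=1.0)          # missing sdlog
        with pytest.raises(ValueError):
            SurvivalSpec("mixture_cure", {"pi": 1.5},
                         base=spec("exponential", rate=1.0))
        with pytest.raises(ValueError):
            SurvivalSpec("royston_parmar", knots=(1.0, 0.5), gamma=(0.1, 0.2))

    @given(shape=st.floats(0.3, 4.0), scale=st.floats(0.5, 60.0))
    @settings(max_examples=40, deadline=None)
    def test_log_logistic_random_parameters(self, shape, scale):
        s = spec("log_logistic", shape=shape, scale=scale)
        t = np.linspace(0.0, 400.0, 401)
        v = s.survival(t)
        assert np.all((v >= 0.0) & (v <= 1.0))
        assert np.all(np.diff(v) <= 1e-12)

    @pytest.mark.parametrize("s", SPECS[:8], ids=lambda s: s.family)
    def test_quantile_inverts_survival(self, s):
        for q in (0.1, 0.5, 0.9):
            t = s.quantile(q)
            if np.isfinite(t):
                assert survival_at(s, float(t)) == pytest.approx(1.0 - q, abs=1e-6)


class TestRoystonParmarBasis:
    def test_derivative_matches_finite_difference(self):
        knots = (0.0, 1.0, 2.0, 3.0)
        x = np.linspace(-0.5, 3.5, 41)
        h = 1e-6
        num = (rp_basis(x + h, knots) - rp_basis(x - h, knots)) / (2 * h)
        np.testing.assert_allclose(rp_basis(x, knots, deriv=True), num,
                                   atol=1e-5)

    def test_default_knots_at_tercile_quantiles(self):
        lt = np.log(np.linspace(1.0, 30.0, 300))
        knots = default_rp_knots(lt, n_internal=2)
        assert len(knots) == 4
        assert knots[0] == pytest.approx(lt.min())
        assert knots[-1] == pytest.approx(lt.max())
        assert np.all(np.diff(knots) > 0)


class TestFitMLE:
    def test_exponential_closed_form(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(10.0, size=400)
        event = (t < 15.0).astype(int)
        obs = np.minimum(t, 15.0)
        fr = fit_mle((obs, event), "exponential")
        oracle = event.sum() / obs.sum()      # events / total exposure
        assert fr.spec.params["rate"] == pytest.approx(oracle, rel=1e-4)

    def test_hand_computed_exponential_likelihood(self):
        """Toy set: events at 1,3,5,7,9, censorings at 2,4,6,8,10:
        lnL(lam) = 5 ln lam - 55 lam, MLE lam = 5/55 = 1/11,
        lnL = -5 ln 11 - 5, AIC = 2 - 2 lnL = 12 + 10 ln 11."""
        times = np.arange(1.0, 11.0)
        events = np.array([1, 0] * 5)
        fr = fit_mle((times, events), "exponential")
        lnl_hand = -5.0 * math.log(11.0) - 5.0
        assert fr.spec.params["rate"] == pytest.approx(1.0 / 11.0, rel=1e-4)
        assert fr.log_likelihood == pytest.approx(lnl_hand, abs=1e-6)
        assert fr.aic == pytest.approx(2.0 - 2.0 * lnl_hand, abs=1e-4)
        assert fr.bic == pytest.approx(math.log(10.0) - 2.0 * lnl_hand,
                                       abs=1e-4)

    def test_log_normal_parameter_recovery(self):
        rng = np.random.default_rng(7)
        t = np.exp(rng.normal(3.6682, 1.6679, size=2000))
        fr = fit_mle((t, np.ones(2000, dtype=int)), "log_normal")
        for name, truth in (("meanlog", 3.6682), ("sdlog", 1.6679)):
            i = fr.param_names.index(name)
            assert abs(fr.spec.params[name] - truth) < 3 * fr.standard_errors[i]

    def test_censoring_aware_fit_equals_uncensored_when_all_events(self):
        rng = np.random.default_rng(3)
        t = np.exp(rng.normal(2.0, 0.8, size=300))
        fr_all = fit_mle((t, np.ones_like(t, dtype=int)), "log_normal")
        # closed form MLE for complete lognormal data
        assert fr_all.spec.params["meanlog"] == pytest.approx(
            np.log(t).mean(), abs=1e-4)
        assert fr_all.spec.params["sdlog"] == pytest.approx(
            np.log(t).std(), rel=1e-3)

    @pytest.mark.parametrize("family,fitter", [
        ("log_normal", LogNormalFitter),
        ("weibull", WeibullFitter),
        ("log_logistic", LogLogisticFitter),
    ])
    def test_agrees_with_lifelines(self, family, fitter):
        """Independent cross-check: same likelihood optimum as lifelines on
        censored data."""
        rng = np.random.default_rng(42)
        t = np.exp(rng.normal(2.2, 0.9, size=500))
        cens = rng.uniform(2.0, 40.0, size=500)
        obs = np.minimum(t, cens)
        ev = (t <= cens).astype(int)
        fr = fit_mle((obs, ev), family)
        lf = fitter().fit(obs, ev)
        assert fr.log_likelihood == pytest.approx(lf.log_likelihood_,
                                                  abs=2e-2)

    def test_all_censored_rejected(self):
        with pytest.raises(FitError):
            fit_mle((np.linspace(1, 10, 20), np.zeros(20, dtype=int)),
                    "exponential")

    def test_too_few_records_rejected(self):
        with pytest.raises(FitError):
            fit_mle((np.array([1.0, 2.0]), np.array([1, 1])), "weibull")

    def test_cure_model_fit_recovers_cure_fraction(self):
        rng = np.random.default_rng(5)
        n = 3000
        cured = rng.uniform(size=n) < 0.35
        t = np.where(cured, np.inf, rng.weibull(1.3, size=n) * 8.0)
        cens = np.full(n, 60.0)
        obs = np.minimum(t, cens)
        ev = (t <= cens).astype(int)
        fr = fit_mle((obs, ev), "mixture_cure")
        assert fr.spec.params["pi"] == pytest.approx(0.35, abs=0.05)

    def test_royston_parmar_fit_tracks_data(self):
        rng = np.random.default_rng(9)
        t = rng.weibull(1.4, size=800) * 12.0
        fr = fit_mle((t, np.ones(800, dtype=int)), "royston_parmar")
        # fitted spline survival close to the empirical survivor function
        ts = np.quantile(t, [0.25, 0.5, 0.75])
        emp = np.array([(t > x).mean() for x in ts])
        np.testing.assert_allclose(fr.spec.survival(ts), emp, atol=0.05)


class TestSelectBest:
    def _fr(self, family, aic, bic, n_obs=100):
        from psmcea.survival import FitResult
        s = spec("exponential", rate=0.1) if family == "exponential" else \
            spec("weibull", shape=1.0, scale=10.0)
        return FitResult(spec=s, log_likelihood=0.0, aic=aic, bic=bic,
                         standard_errors=(0.1,), n_obs=n_obs)

    def test_minimum_aic_wins(self):
        a = self._fr("exponential", 958.0, 960.0)
        b = self._fr("weibull", 709.0, 715.0)
        assert select_best([a, b]) is b

    def test_single_element(self):
        a = self._fr("exponential", 100.0, 101.0)
        assert select_best([a]) is a

    def test_tie_broken_by_bic(self):
        a = self._fr("exponential", 500.0, 510.0)
        b = self._fr("weibull", 500.0, 505.0)
        assert select_best([a, b]) is b

    def test_mismatched_datasets_rejected(self):
        a = self._fr("exponential", 500.0, 505.0, n_obs=100)
        b = self._fr("weibull", 400.0, 405.0, n_obs=200)
        with pytest.raises(ValueError):
            select_best([a, b])


class TestRestrictedMean:
    def test_degenerate_flat_curve(self):
        s = spec("exponential", rate=1e-12)
        assert restricted_mean(s, 120.0, 0.0) == pytest.approx(120.0, rel=1e-9)

    def test_exponential_closed_form(self):
        s = spec("exponential", rate=0.2)
        assert restricted_mean(s, 1e4, 0.0) == pytest.approx(5.0, rel=1e-6)

    def test_matches_cycle_sum_engine(self):
        """Quadrature oracle vs the PSM cycle sum under matching conventions
        (continuous discounting, midpoint evaluation)."""
        from psmcea.engine import (ModelSettings, compute_occupancy,
                                   discounted_life_years)
        s = spec("log_normal", meanlog=3.6682, sdlog=1.6679)
        settings = ModelSettings(horizon_years=20.0, annual_discount=0.05,
                                 eval_point="mid", discounting="continuous")
        trace = compute_occupancy(s, s, settings)
        ly_engine = discounted_life_years(trace)
        ly_quad = restricted_mean(s, 240.0, 0.05) / 12.0
        assert abs(ly_engine - ly_quad) < 0.5 * settings.cycle_years

    def test_invalid_inputs(self):
        s = spec("exponential", rate=0.1)
        with pytest.raises(ValueError):
            restricted_mean(s, -1.0)
        with pytest.raises(ValueError):
            restricted_mean(s, 10.0, annual_discount=0.5)
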