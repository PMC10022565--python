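"""Gompertz fitting, AIC selection and piecewise death-time sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from mhsim import Gompertz, ParameterError, fit_parametric, sample_death_time, select_by_aic
from mhsim.survival import (
    ParametricFit,
    gompertz_cumhaz,
    gompertz_inv_cumhaz,
    sample_death_times,
)

STATUS = {"none": Gompertz(0.08, 1e-4), "any": Gompertz(0.08, 4e-4)}


def _simulate_gompertz(shape, rate, n, censor_at, rng):
    u = rng.uniform(size=n)
    t = gompertz_inv_cumhaz(-np.log1p(-u), shape, rate)
    event = (t <= censor_at).astype(int)
    return np.minimum(t, censor_at), event


class TestSampling:
    def test_closed_form_inverse_no_switch(self):
        g = STATUS["none"]
        for u in (0.001, 0.1, 0.5, 0.9, 0.999):
            expected = (1.0 / g.shape) * np.log(
                1.0 - g.shape * np.log(1.0 - u) / g.rate
            )
            assert sample_death_time(u, STATUS) == pytest.approx(expected, abs=1e-10)

    def test_degenerate_switch_identical_parameters(self):
        both = {"none": STATUS["none"], "any": STATUS["none"]}
        for u in (0.05, 0.5, 0.95):
            assert sample_death_time(u, both, status_switch_age=14.0) == pytest.approx(
                sample_death_time(u, both), abs=1e-12
            )

    def test_switch_to_higher_hazard_never_delays_death(self):
        for u in np.linspace(0.01, 0.99, 25):
            no_switch = sample_death_time(u, STATUS)
            switched = sample_death_time(u, STATUS, status_switch_age=14.0)
            assert switched <= no_switch + 1e-12

    def test_matches_numeric_inversion_oracle(self):
        """Brute-force root finding on the piecewise cumulative hazard."""
        g0, g1 = STATUS["none"], STATUS["any"]

        def cumhaz(t, s):
            if t < s:
                return gompertz_cumhaz(t, g0.shape, g0.rate)
            return gompertz_cumhaz(s, g0.shape, g0.rate) + (
                gompertz_cumhaz(t, g1.shape, g1.rate)
                - gompertz_cumhaz(s, g1.shape, g1.rate)
            )

        for u in (0.1, 0.5, 0.9):
            for s in (5.0, 14.0, 60.0):
                target = -np.log1p(-u)
                oracle = optimize.brentq(
                    lambda t: cumhaz(t, s) - target, 1e-9, 500.0, xtol=1e-10
                )
                ours = sample_death_time(u, STATUS, status_switch_age=s)
                assert ours == pytest.approx(oracle, abs=1e-8)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        u=st.floats(0.001, 0.999),
        s1=st.floats(1.0, 100.0),
        delta=st.floats(0.1, 50.0),
    )
    def test_earlier_switch_to_higher_hazard_never_later(self, u, s1, delta):
        t_early = sample_death_time(u, STATUS, status_switch_age=s1)
        t_late = sample_death_time(u, STATUS, status_switch_age=s1 + delta)
        assert t_early <= t_late + 1e-9

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(u1=st.floats(0.001, 0.998), du=st.floats(1e-6, 0.001))
    def test_monotone_in_u(self, u1, du):
        s = 20.0
        assert sample_death_time(u1, STATUS, s) <= sample_death_time(
            min(u1 + du, 0.9999), STATUS, s
        ) + 1e-12

    def test_continuity_in_switch_age(self):
        u = 0.7
        base = sample_death_time(u, STATUS, status_switch_age=30.0)
        for eps in (1e-6, 1e-8):
            assert sample_death_time(u, STATUS, 30.0 + eps) == pytest.approx(
                base, abs=1e-3
            )

    def test_empirical_survivor_matches_analytic_ks(self):
        """100,000 inverse-CDF draws pass a KS test against the analytic
        Gompertz distribution at alpha = 0.01."""
        g = STATUS["none"]
        rng = np.random.default_rng(99)
        u = rng.uniform(1e-12, 1 - 1e-12, size=100_000)
        draws = sample_death_times(u, g, g)
        cdf = lambda t: 1.0 - np.exp(-gompertz_cumhaz(t, g.shape, g.rate))
        d, _ = stats.kstest(draws, cdf)
        assert d < 1.628 / np.sqrt(len(draws))  # alpha = 0.01 critical value

    def test_invalid_uniform_rejected(self):
        with pytest.raises(ParameterError):
            sample_death_time(0.0, STATUS)


class TestFitting:
    def test_gompertz_parameter_recovery_within_3_se(self):
        shape, rate = 0.09, 1e-4
        rng = np.random.default_rng(7)
        t, d = _simulate_gompertz(shape, rate, 20_000, censor_at=30.0, rng=rng)
        fit = fit_parametric(t, d, family="gompertz")
        p, se = fit.params[None], fit.se[None]
        assert abs(p["shape"] - shape) < 3 * se["shape"]
        assert abs(p["rate"] - rate) < 3 * se["rate"]

    def test_gompertz_on_exponential_data_nests_cleanly(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(1 / 0.02, size=5_000)
        d = (t <= 40.0).astype(int)
        t = np.minimum(t, 40.0)
        gomp = fit_parametric(t, d, family="gompertz")
        expo = fit_parametric(t, d, family="exponential")
        assert abs(gomp.params[None]["shape"]) < 0.01
        assert expo.aic <= gomp.aic + 2.0 + 1e-9

    def test_all_censored_raises(self):
        with pytest.raises(ParameterError, match="zero events"):
            fit_parametric([1.0, 2.0, 3.0], [0, 0, 0], family="gompertz")

    def test_grouped_fit_estimates_each_group(self):
        rng = np.random.default_rng(5)
        t1, d1 = _simulate_gompertz(0.08, 1e-4, 4_000, 80.0, rng)
        t2, d2 = _simulate_gompertz(0.08, 5e-4, 4_000, 80.0, rng)
        t = np.concatenate([t1, t2])
        d = np.concatenate([d1, d2])
        g = np.array(["a"] * 4_000 + ["b"] * 4_000)
        fit = fit_parametric(t, d, groups=g, family="gompertz")
        assert fit.n_params == 4
        assert fit.params["b"]["rate"] > fit.params["a"]["rate"]

    def test_weibull_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        t = rng.weibull(1.5, size=3_000) * 20.0
        d = (t <= 25.0).astype(int)
        t = np.minimum(t, 25.0)
        ours = fit_parametric(t, d, family="weibull")
        wf = lifelines.WeibullFitter().fit(t, d)
        assert ours.params[None]["rho"] == pytest.approx(wf.rho_, rel=1e-4)
        assert ours.params[None]["lambda"] == pytest.approx(wf.lambda_, rel=1e-4)
        assert ours.log_likelihood == pytest.approx(
            wf.log_likelihood_, rel=1e-6
        )


class TestSelectByAic:
    def _fit(self, aic, k):
        return ParametricFit(
            family=f"f{k}", params={}, se={},
            log_likelihood=k - aic / 2.0, n_params=k,
        )

    def test_minimum_aic_wins(self):
        a, b = self._fit(100.0, 2), self._fit(98.0, 2)
        assert select_by_aic([a, b]) is b

    def test_tie_broken_by_fewer_parameters(self):
        a, b = self._fit(100.0, 2), self._fit(100.0, 1)
        assert select_by_aic([a, b]) is b

    def test_single_fit_returned(self):
        a = self._fit(50.0, 1)
        assert select_by_aic([a]) is a

    def test_empty_list_raises(self):
        with pytest.raises(ParameterError):
            select_by_aic([])
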