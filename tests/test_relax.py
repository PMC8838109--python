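"""Relaxation analysis: decay fits, Arrhenius fits, BPP model and inversion."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spindyn as sd
from spindyn.exceptions import (
    InvalidParameterError, NoSolutionError, WindowError,
)
from spindyn.relax import bpp_max, classify_branch


class TestDecayFit:
    def test_noiseless_long_t1_recovered(self):
        curve = sd.gen_decay(6.1, np.geomspace(0.1, 30.0, 10))
        t1, _ = sd.fit_decay(curve)
        assert t1 == pytest.approx(6.1, rel=1e-3)

    def test_two_point_exact_solution(self):
        curve = sd.DecayCurve(np.array([0.0, 1.0]), np.array([1.0, math.exp(-1.0)]))
        t1, _ = sd.fit_decay(curve)
        assert t1 == pytest.approx(1.0, rel=1e-12)

    def test_monte_carlo_calibration(self):
        # mean estimate within 1% of truth; spread consistent with stderr
        ests, errs = [], []
        for seed in range(100):
            c = sd.gen_decay(1.0, np.geomspace(0.02, 5.0, 12), 0.05, seed=seed)
            t1, se = sd.fit_decay(c)
            ests.append(t1)
            errs.append(se)
        assert np.mean(ests) == pytest.approx(1.0, rel=0.01)
        assert np.std(ests) == pytest.approx(np.mean(errs), rel=0.35)

    def test_constant_intensities_rejected(self):
        with pytest.raises(InvalidParameterError):
            sd.ExponentialDecayModel(np.arange(4.0), np.ones(4)).fit()

    def test_summary_mentions_estimate(self):
        res = sd.ExponentialDecayModel.from_curve(
            sd.gen_decay(0.5, np.geomspace(0.01, 3, 8))).fit()
        assert "T1" in res.summary()


class TestArrheniusFit:
    def test_slow_branch_30_kJ(self):
        s = sd.gen_rate_series(sd.GroundTruth(30.0, 1.0), np.linspace(235, 270, 8), "slow")
        r = sd.arrhenius_fit(s)
        assert r.e_star == pytest.approx(30.0, rel=1e-6)
        assert r.branch == "slow"

    def test_fast_branch_4p1_kJ(self):
        s = sd.gen_rate_series(sd.GroundTruth(4.1, 1.0), np.linspace(280, 330, 8), "fast")
        r = sd.arrhenius_fit(s)
        assert r.e_star == pytest.approx(4.1, rel=1e-6)
        assert r.branch == "fast"

    def test_constant_rates_flagged_flat(self):
        r = sd.arrhenius_fit(sd.RateSeries(np.array([240.0, 260.0, 280.0]),
                                           np.array([2.0, 2.0, 2.0])))
        assert r.e_star == 0.0
        assert r.r_squared == 0.0
        assert r.flat

    def test_window_restricts_fit(self):
        t = np.linspace(230, 320, 10)
        s = sd.gen_rate_series(sd.GroundTruth(18.0, 1.0), t, "fast")
        r = sd.arrhenius_fit(s, window=(260, 320))
        assert r.n == int(np.sum((t >= 260) & (t <= 320)))
        assert r.e_star == pytest.approx(18.0, rel=1e-6)

    def test_window_over_rate_maximum_warns(self):
        # ∧-shaped series: rising then falling ln R
        t = np.linspace(230, 310, 9)
        params = sd.SpectralDensityParams()
        # correlation time sweeping through the T1 minimum with temperature
        taus = 1e-8 * np.exp(-(t - 230) / 11.6)
        rates = np.array([sd.bpp_rate(replace(params, tau_c=tau)) for tau in taus])
        with pytest.warns(UserWarning, match="separate windows"):
            sd.arrhenius_fit(sd.RateSeries(t, rates))

    def test_too_few_points(self):
        with pytest.raises(WindowError):
            sd.arrhenius_fit(sd.RateSeries(np.array([250.0, 260.0, 270.0]),
                                           np.array([1.0, 2.0, 3.0])),
                             window=(255, 265))

    @pytest.mark.parametrize("branch", ["fast", "slow"])
    def test_random_pairs_zero_noise_exact(self, branch, rng):
        for _ in range(20):
            e_true = rng.uniform(2.0, 60.0)
            a_true = 10.0 ** rng.uniform(-2, 4)
            s = sd.gen_rate_series(sd.GroundTruth(e_true, a_true),
                                   np.linspace(230, 320, 8), branch)
            r = sd.arrhenius_fit(s)
            assert r.e_star == pytest.approx(e_true, rel=1e-3)
            assert r.branch == branch


class TestBPP:
    def test_extreme_narrowing_limit(self):
        p = replace(sd.SpectralDensityParams(), tau_c=1e-15)
        assert sd.bpp_rate(p) < 1e-4

    def test_unimodal_positive_continuous(self):
        taus = np.logspace(-13, -6, 2000)
        rates = np.array([sd.bpp_rate(replace(sd.SpectralDensityParams(), tau_c=t))
                          for t in taus])
        assert np.all(rates > 0)
        d = np.diff(rates)
        sign_changes = np.sum(np.diff(np.sign(d)) != 0)
        assert sign_changes == 1  # single interior maximum

    def test_lab_frame_maximum_near_wc_tau_079(self):
        p = sd.SpectralDensityParams()
        tau_max, _ = bpp_max(p)
        wc = 2 * np.pi * p.nu_c * 1e6
        assert wc * tau_max == pytest.approx(0.79, rel=0.05)

    def test_maximum_agrees_with_symbolic_derivative_oracle(self):
        # independent oracle: differentiate the closed form with sympy
        import sympy as sp

        p = sd.SpectralDensityParams()
        tau = sp.symbols("tau", positive=True)
        wc = 2 * sp.pi * p.nu_c * 1e6
        wh = 2 * sp.pi * p.nu_h * 1e6
        expr = (tau / (1 + (wh - wc) ** 2 * tau**2)
                + 3 * tau / (1 + wc**2 * tau**2)
                + 6 * tau / (1 + (wh + wc) ** 2 * tau**2))
        dfun = sp.lambdify(tau, sp.diff(expr, tau), "numpy")
        from scipy.optimize import brentq

        tau_oracle = brentq(dfun, 1e-12, 1e-8)
        tau_impl, _ = bpp_max(p)
        assert tau_impl == pytest.approx(tau_oracle, rel=1e-4)

    def test_rotating_frame_adds_low_frequency_term(self):
        p = replace(sd.SpectralDensityParams(), tau_c=1.6e-5)
        r_lab = sd.bpp_rate(p, frame="lab")
        r_rot = sd.bpp_rate(p, frame="rotating", spin_lock_nu=62.5)
        assert r_rot > 10 * r_lab  # J(2 w1) dominates for slow motion

    def test_methyl_t1_band_maps_to_published_tau_band(self):
        # T1 0.4-1.1 s at 125.7 MHz -> tau_c 4.8e-11 to 1.1e-10 s (25% band)
        p = sd.SpectralDensityParams()
        tau_short = sd.invert_rate_to_tau(1.0 / 1.1, p, branch="fast")
        tau_long = sd.invert_rate_to_tau(1.0 / 0.4, p, branch="fast")
        assert tau_short == pytest.approx(4.8e-11, rel=0.25)
        assert tau_long == pytest.approx(1.1e-10, rel=0.25)


class TestInversion:
    def test_round_trip_fast_branch(self):
        p = replace(sd.SpectralDensityParams(), tau_c=1e-10)
        rate = sd.bpp_rate(p)
        assert sd.invert_rate_to_tau(rate, p, branch="fast") == pytest.approx(1e-10, rel=1e-6)

    def test_rate_at_maximum_both_branches_agree(self):
        p = sd.SpectralDensityParams()
        tau_max, r_max = bpp_max(p)
        assert sd.invert_rate_to_tau(r_max, p, branch="fast") == pytest.approx(tau_max, rel=1e-4)
        assert sd.invert_rate_to_tau(r_max, p, branch="slow") == pytest.approx(tau_max, rel=1e-4)

    def test_half_maximum_gives_two_distinct_roots(self):
        p = sd.SpectralDensityParams()
        _, r_max = bpp_max(p)
        t_fast = sd.invert_rate_to_tau(r_max / 2, p, branch="fast")
        t_slow = sd.invert_rate_to_tau(r_max / 2, p, branch="slow")
        assert t_fast < t_slow
        for t in (t_fast, t_slow):
            assert sd.bpp_rate(replace(p, tau_c=t)) == pytest.approx(r_max / 2, rel=1e-6)

    def test_rate_above_maximum_raises_naming_it(self):
        p = sd.SpectralDensityParams()
        _, r_max = bpp_max(p)
        with pytest.raises(NoSolutionError, match="maximum"):
            sd.invert_rate_to_tau(2 * r_max, p)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(frac=st.floats(min_value=0.0, max_value=1.0),
           branch_fast=st.booleans())
    def test_inversion_is_identity_on_each_branch(self, frac, branch_fast):
        p = sd.SpectralDensityParams()
        tau_max, _ = bpp_max(p)
        if branch_fast:
            tau = 0.5 * tau_max * 10.0 ** (-3.0 * frac)  # well below the maximum
            branch = "fast"
        else:
            tau = 2.0 * tau_max * 10.0 ** (3.0 * frac)  # well above the maximum
            branch = "slow"
        rate = sd.bpp_rate(replace(p, tau_c=tau))
        assert sd.invert_rate_to_tau(rate, p, branch=branch) == pytest.approx(tau, rel=1e-6)


class TestMatchingRuleAndBranch:
    @pytest.mark.parametrize("nu_khz,tau", [(62.5, 1.6e-5), (100.0, 1.0e-5), (50.0, 2.0e-5)])
    def test_reciprocal_rule(self, nu_khz, tau):
        assert sd.r1rho_max_tau(nu_khz) == pytest.approx(tau, rel=1e-12)

    def test_branch_classification_around_t1_minimum(self):
        assert classify_branch(8.0e-9) == "slow"
        assert classify_branch(5.0e-11) == "fast"
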