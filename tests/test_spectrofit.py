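"""Transient-absorption band dynamics and decay fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from photodipole._pso import PSOConfig, pso_minimize
from photodipole.spectrofit import (TAMap, gsb_band_dynamics, fit_monoexp_pso,
                                    pileup_steady_offset, fit_two_population)
from photodipole.synthetic_data import gen_ta_fixture


def _band_map(tau=42e-6, center=520.0, noise_sd=0.0, seed=None):
    wl = np.arange(400.0, 641.0, 2.0)
    delays = np.linspace(2e-6, 8 * tau, 150)
    band = np.exp(-0.5 * ((wl - center) / 20.0) ** 2)
    dTT = np.exp(-delays / tau)[:, None] * band[None, :]
    if noise_sd:
        dTT = dTT + np.random.default_rng(seed).normal(0, noise_sd, dTT.shape)
    return TAMap(wavelengths=wl, delays=delays, dTT=dTT)


class TestBandDynamics:
    def test_extracts_injected_kinetics(self):
        m = _band_map()
        trace = gsb_band_dynamics(m, 520.0, 4.0)
        scale = trace[0] / np.exp(-m.delays[0] / 42e-6)
        assert np.max(np.abs(trace - scale * np.exp(-m.delays / 42e-6))) < 1e-10

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            gsb_band_dynamics(_band_map(), 900.0, 5.0)

    def test_nine_channel_average_shrinks_noise_threefold(self):
        """Averaging 9 i.i.d.-noise channels reduces the SD by ~3."""
        sds = []
        for seed in range(200):
            m = _band_map(noise_sd=1e-3, seed=seed)
            # flat spectral region far from the band: pure noise
            trace = gsb_band_dynamics(m, 420.0, 8.0)   # 9 channels at 2 nm
            sds.append(trace.std(ddof=1))
        assert np.mean(sds) == pytest.approx(1e-3 / 3.0, rel=0.2)


class TestMonoexpFit:
    def test_noiseless_recovery(self):
        t = np.linspace(0, 2.4e-3, 160)
        y = 1.7 * np.exp(-t / 300e-6) + 0.2
        m = fit_monoexp_pso(t, y, pso_config=PSOConfig(seed=5))
        assert abs(m.tau - 300e-6) / 300e-6 < 1e-3

    def test_noisy_recovery_within_5_percent(self):
        t = np.linspace(0, 300e-6, 150)
        rng = np.random.default_rng(2024)
        y = 2.0 * np.exp(-t / 42e-6) * (1 + rng.normal(0, 0.05, t.size)) + 0.1
        m = fit_monoexp_pso(t, y, pso_config=PSOConfig(seed=7))
        assert abs(m.tau - 42e-6) / 42e-6 < 0.05

    def test_model_homogeneity_under_amplitude_scaling(self):
        t = np.linspace(0, 1.0, 120)
        y = 3.0 * np.exp(-t / 0.21) + 0.4
        m1 = fit_monoexp_pso(t, y, pso_config=PSOConfig(seed=9))
        m10 = fit_monoexp_pso(t, 10 * y, pso_config=PSOConfig(seed=9))
        assert m10.tau == pytest.approx(m1.tau, rel=1e-9)
        assert m10.A == pytest.approx(10 * m1.A, rel=1e-6)

    def test_constant_trace_flagged(self):
        t = np.linspace(0, 1.0, 64)
        m = fit_monoexp_pso(t, np.full_like(t, 0.3), pso_config=PSOConfig(seed=1))
        assert m.flags.get("tau_unidentifiable")

    def test_pso_never_worse_than_initial_swarm(self):
        """Monotone improvement: the returned SSE never exceeds the best
        initial particle's, and the best-history is nonincreasing."""
        t = np.linspace(0, 1.0, 100)
        y = np.exp(-t / 0.1) + np.random.default_rng(0).normal(0, 0.05, t.size)

        def sse(theta):
            model = theta[:, 0:1] * np.exp(-t[None, :] / theta[:, 1:2]) + theta[:, 2:3]
            r = model - y[None, :]
            return np.sum(r * r, axis=1)

        res = pso_minimize(sse, [(-2, 2), (1e-3, 10), (-1, 1)],
                           PSOConfig(seed=4, iters=120))
        assert res.fun <= res.best_history[0]
        assert np.all(np.diff(res.best_history) <= 1e-15)

    def test_lifetime_recovery_statistics(self):
        """100 seeded replicates at 5% multiplicative noise: median
        relative error < 3%, 95th percentile < 10%, for lifetimes spanning
        the fast-isomerisation and both cis-decay regimes."""
        for tau, span in ((2.2, 20.0), (42e-6, 320e-6), (300e-6, 2.4e-3)):
            t = np.linspace(span / 150, span, 150)
            clean = np.exp(-t / tau)
            errs = []
            for seed in range(100):
                rng = np.random.default_rng(10_000 + seed)
                y = clean * (1 + rng.normal(0, 0.05, t.size))
                m = fit_monoexp_pso(t, y,
                                    pso_config=PSOConfig(seed=seed, swarm=30,
                                                         iters=150, patience=40))
                errs.append(abs(m.tau - tau) / tau)
            assert np.median(errs) < 0.03
            assert np.quantile(errs, 0.95) < 0.10


class TestPileup:
    def test_fast_decay_has_no_pileup(self):
        assert pileup_steady_offset(1.0, 1.0 / 20, 1.0) < 2.1e-9

    @pytest.mark.parametrize("tau_over_T,expected", [
        (1.0, 0.58198), (10.0, 9.5083),
    ])
    def test_reference_values(self, tau_over_T, expected):
        assert pileup_steady_offset(1.0, tau_over_T, 1.0) == \
            pytest.approx(expected, abs=5e-5)

    @given(A=st.floats(0.01, 10), tau=st.floats(0.05, 5), T_rep=st.floats(0.1, 2))
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_closed_form_equals_recurrence_limit(self, A, tau, T_rep):
        r = 0.0
        decay = np.exp(-T_rep / tau)
        for _ in range(3000):
            r = (r + A) * decay
        assert abs(pileup_steady_offset(A, tau, T_rep) - r) < 1e-10 * max(1.0, r)

    def test_slow_limit_scales_as_tau_over_T(self):
        assert pileup_steady_offset(1.0, 500.0, 1.0) == \
            pytest.approx(500.0, rel=2e-3)

    def test_pileup_fit_recovers_lifetime_with_residual_baseline(self):
        tau, T_rep = 0.4, 0.5            # 2 Hz pumping, slow decay
        t = np.linspace(0, 2.0, 200)
        r_inf = pileup_steady_offset(1.0, tau, T_rep)
        y = 1.0 * np.exp(-t / tau) + r_inf
        m = fit_monoexp_pso(t, y, pso_config=PSOConfig(seed=2),
                            pileup=True, T_rep=T_rep)
        assert abs(m.tau - tau) / tau < 1e-3
        assert m.baseline == pytest.approx(r_inf, rel=1e-2)


class TestTwoPopulation:
    def test_pure_fixed_component_flagged(self):
        t = np.linspace(0, 300e-6, 200)
        y = 1.0 * np.exp(-t / 42e-6)
        fit = fit_two_population(t, y, 42e-6, seed=1)
        assert fit.f > 0.99
        assert fit.flags.get("tau_free_unidentifiable") or \
            fit.flags.get("lifetimes_degenerate")

    def test_noiseless_mixture_recovered_within_1_percent(self):
        t = np.linspace(0, 1.5e-3, 300)
        y = 1.0 * (0.3 * np.exp(-t / 42e-6) + 0.7 * np.exp(-t / 300e-6)) + 0.05
        fit = fit_two_population(t, y, 42e-6, seed=3)
        assert abs(fit.f - 0.3) < 0.01
        assert abs(fit.tau_free - 300e-6) / 300e-6 < 0.01

    def test_amplitude_weighted_mean_lifetime(self):
        """A 50/50 mixture of 42 and 300 us has mean lifetime 171 us --
        the sense in which a micelle suspension's lifetime is an average."""
        t = np.linspace(0, 1.5e-3, 300)
        y = 0.5 * np.exp(-t / 42e-6) + 0.5 * np.exp(-t / 300e-6)
        fit = fit_two_population(t, y, 42e-6, seed=5)
        assert fit.mean_lifetime == pytest.approx(171e-6, rel=0.01)


class TestClosedLoopOnSyntheticMaps:
    def test_us_fixture_lifetime_recovered(self):
        m = gen_ta_fixture("water", "us", noise_sd=0.0, seed=0)
        trace = gsb_band_dynamics(m, m.meta["gsb_center_nm"], 10.0)
        fit = fit_monoexp_pso(m.delays, trace, pso_config=PSOConfig(seed=0))
        assert abs(fit.tau - m.meta["tau_s"]) / m.meta["tau_s"] < 1e-3
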