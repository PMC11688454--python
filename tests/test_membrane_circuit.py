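"""Equivalent-circuit membrane model."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from photodipole.photokinetics import (LightProtocol, PhotoswitchParams,
                                       simulate_populations, PopulationTrace)
from photodipole.membrane_circuit import (MembraneCircuitParams, TimeTrace,
                                          surface_potential_trace,
                                          simulate_current_clamp,
                                          simulate_voltage_clamp,
                                          peak_metrics,
                                          estimate_capacitance_from_step)
from photodipole.membrane_circuit import _cc_response
from photodipole.synthetic_data import gen_capacitance_step, GeneratorTruth


def _step_trace(dt=1e-4, total=0.2, t_step=0.05, level=5e-3):
    t = np.arange(0.0, total, dt)
    return TimeTrace(t=t, y=np.where(t >= t_step, level, 0.0), units="V")


class TestSurfacePotential:
    def test_zero_cis_gives_zero(self, default_circuit):
        t = np.linspace(0, 0.1, 101)
        pop = PopulationTrace(t=t, n_trans=np.ones_like(t), n_cis=np.zeros_like(t))
        dvs = surface_potential_trace(pop, default_circuit, 0.25)
        assert np.all(dvs.y == 0.0)

    def test_direct_product(self):
        circ = MembraneCircuitParams(alpha=10e-3)
        t = np.linspace(0, 0.1, 101)
        n_cis = np.full_like(t, 0.4)
        pop = PopulationTrace(t=t, n_trans=1 - n_cis, n_cis=n_cis)
        dvs = surface_potential_trace(pop, circ, 0.25)
        assert dvs.y[50] == pytest.approx(1.0e-3, rel=1e-12)

    def test_peak_times_coincide(self, default_params, default_circuit):
        pop = simulate_populations(LightProtocol.pulse(0.01, 0.02, 0.05, 105.0),
                                   default_params)
        dvs = surface_potential_trace(pop, default_circuit, 0.07)
        assert np.argmax(dvs.y) == np.argmax(pop.n_cis)


class TestCurrentClamp:
    def test_no_drive_stays_at_rest(self, default_circuit):
        t = np.arange(0, 0.1, 1e-4)
        dvs = TimeTrace(t=t, y=np.zeros_like(t), units="V")
        vm = simulate_current_clamp(dvs, default_circuit)
        assert np.allclose(vm.y, default_circuit.V_rest, atol=1e-15)

    def test_step_with_capacitive_coupling_only_matches_closed_form(self):
        """With G_s = 0 a surface-potential step produces the pure
        capacitive transient (C_s/C_m) dVs exp(-t/tau_m)."""
        circ = MembraneCircuitParams(G_s=0.0)
        dvs = _step_trace()
        vm = simulate_current_clamp(dvs, circ)
        t = dvs.t
        expect = np.where(
            t >= 0.05,
            (circ.C_s / circ.C_m) * 5e-3 * np.exp(-(t - 0.05) / circ.tau_m), 0.0)
        assert np.max(np.abs(vm.y - circ.V_rest - expect)) < 1e-9 * 5e-3

    def test_superposition(self, default_circuit):
        rng = np.random.default_rng(3)
        t = np.arange(0, 0.1, 1e-4)
        a = np.cumsum(rng.normal(size=t.size)) * 1e-5
        b = np.cumsum(rng.normal(size=t.size)) * 1e-5
        dt = 1e-4
        resp = _cc_response(a + b, dt, default_circuit)
        parts = _cc_response(a, dt, default_circuit) + _cc_response(b, dt, default_circuit)
        assert np.max(np.abs(resp - parts)) <= 1e-9

    def test_matches_adaptive_ode_oracle(self, default_circuit):
        """Exact discrete update equals high-accuracy RK45 under the same
        zero-order-hold reading of the sampled drive."""
        circ = default_circuit
        dvs = _step_trace()
        dt = dvs.dt
        c = (circ.G_s - circ.C_s / (circ.R_m * circ.C_m)) / circ.C_m

        def rhs(tt, w):
            k = min(int(tt / dt), dvs.y.size - 1)
            return -w / circ.tau_m + c * dvs.y[k]

        sol = solve_ivp(rhs, (0, dvs.t[-1]), [0.0], t_eval=dvs.t,
                        rtol=1e-10, atol=1e-14, max_step=dt)
        vm = simulate_current_clamp(dvs, circ)
        dvm = vm.y - circ.V_rest
        ref = sol.y[0] + (circ.C_s / circ.C_m) * dvs.y
        assert np.max(np.abs(dvm - ref)) < 1e-8 * 5e-3

    def test_zero_net_charge_over_full_cycle_without_conductive_path(
            self, default_params):
        """With G_s = 0 the membrane charge moved in during light-on is
        returned after light-off: integral of dV_m vanishes."""
        circ = MembraneCircuitParams(G_s=0.0)
        pop = simulate_populations(LightProtocol.pulse(0.01, 0.02, 0.5, 105.0),
                                   default_params, dt_out=1e-5)
        dvs = surface_potential_trace(pop, circ, 0.07)
        vm = simulate_current_clamp(dvs, circ)
        dvm = vm.y - circ.V_rest
        net = np.trapezoid(dvm, vm.t)
        scale = np.trapezoid(np.abs(dvm), vm.t)
        assert abs(net) / scale < 1e-4

    def test_amplitude_linear_in_alpha(self, default_params):
        pop = simulate_populations(LightProtocol.pulse(0.05, 0.02, 0.2, 105.0),
                                   default_params)
        amps = []
        for alpha in (0.1, 0.2):
            circ = MembraneCircuitParams(alpha=alpha)
            dvs = surface_potential_trace(pop, circ, 0.07)
            vm = simulate_current_clamp(dvs, circ)
            amps.append(np.max(vm.y - circ.V_rest))
        assert amps[1] == pytest.approx(2 * amps[0], rel=1e-9)

    def test_peak_within_10ms_and_signed_transients(self, default_params,
                                                    default_circuit, default_truth):
        """Default calibrated parameters: depolarizing peak within 10 ms of
        light onset, then a post-pulse hyperpolarizing transient smaller
        in magnitude."""
        pop = simulate_populations(LightProtocol.pulse(0.1, 0.02, 0.4, 105.0),
                                   default_params)
        asym = default_truth.asym_at(default_circuit.V_rest)
        dvs = surface_potential_trace(pop, default_circuit, asym)
        vm = simulate_current_clamp(dvs, default_circuit, filter_cutoff_hz=2000.0)
        depol, hyper, t_peak = peak_metrics(vm, 0.1, 0.12)
        assert 0.0 < t_peak <= 0.010
        assert depol > 0 and hyper < 0
        assert abs(hyper) < depol


class TestVoltageClamp:
    def test_dark_trace_is_pure_leak(self, default_circuit):
        t = np.arange(0, 0.1, 1e-4)
        dvs = TimeTrace(t=t, y=np.zeros_like(t), units="V",
                        dy_dt=np.zeros_like(t))
        iv = simulate_voltage_clamp(dvs, default_circuit, -0.060)
        leak = (-0.060 - default_circuit.V_rest) / default_circuit.R_m
        assert np.allclose(iv.y, leak, atol=1e-18)

    def test_capacitive_charge_conservation(self, default_params):
        """The ON-transient integral of the light-evoked current equals
        -C_s * dV_s,ss (trapezoid quadrature, 1 us grid)."""
        circ = MembraneCircuitParams(G_s=0.0)
        pop = simulate_populations(LightProtocol.pulse(0.002, 0.02, 0.001, 105.0),
                                   default_params, dt_out=1e-6)
        dvs = surface_potential_trace(pop, circ, 0.07)
        iv = simulate_voltage_clamp(dvs, circ, -0.060)
        evoked = iv.y - (-0.060 - circ.V_rest) / circ.R_m
        # integrate the ON transient up to the last sample before light-off
        # (the drive derivative is discontinuous at the off edge)
        on = (iv.t >= 0.002) & (iv.t <= 0.022 - 1e-6)
        Q = np.trapezoid(evoked[on], iv.t[on])
        target = -circ.C_s * dvs.y[on][-1]
        assert abs(Q - target) / abs(target) < 1e-6

    def test_fast_peak_then_plateau(self, default_params, default_circuit,
                                    default_truth):
        """Default parameters give an inward photocurrent peaking within
        ~2 ms and settling to a nonzero plateau for the rest of the pulse."""
        pop = simulate_populations(LightProtocol.pulse(0.05, 0.02, 0.1, 105.0),
                                   default_params)
        asym = default_truth.asym_at(default_circuit.V_rest)
        dvs = surface_potential_trace(pop, default_circuit, asym)
        iv = simulate_voltage_clamp(dvs, default_circuit, -0.060,
                                    filter_cutoff_hz=2000.0)
        evoked = iv.y - iv.y[0]
        on = (iv.t >= 0.05) & (iv.t <= 0.07)
        t_pk = iv.t[on][np.argmin(evoked[on])] - 0.05
        assert t_pk <= 0.005
        plateau = evoked[np.searchsorted(iv.t, 0.0695)]
        assert plateau < 0                       # sustained inward component
        assert abs(plateau) < abs(evoked[on].min())

    def test_plateau_equals_conductive_term(self, default_params):
        circ = MembraneCircuitParams()
        pop = simulate_populations(LightProtocol.pulse(0.01, 0.05, 0.01, 105.0),
                                   default_params)
        dvs = surface_potential_trace(pop, circ, 0.07)
        iv = simulate_voltage_clamp(dvs, circ, circ.V_rest)
        k = np.searchsorted(iv.t, 0.059)         # late in the pulse, dVs' ~ 0
        assert iv.y[k] == pytest.approx(-circ.G_s * dvs.y[k], rel=1e-6)


class TestPeakMetrics:
    def test_constant_trace(self):
        t = np.arange(0, 1.0, 1e-3)
        tr = TimeTrace(t=t, y=np.full_like(t, -0.035), units="V")
        assert peak_metrics(tr, 0.3, 0.5) == (0.0, 0.0, 0.0)

    def test_triangular_pulse_apex(self):
        t = np.arange(0, 1.0, 1e-4)
        y = np.full_like(t, -0.040)
        apex_t, apex = 0.308, 2.5e-3
        rise = (t >= 0.3) & (t <= apex_t)
        fall = (t > apex_t) & (t <= 0.316)
        y[rise] += apex * (t[rise] - 0.3) / 0.008
        y[fall] += apex * (0.316 - t[fall]) / 0.008
        tr = TimeTrace(t=t, y=y, units="V")
        depol, hyper, t_peak = peak_metrics(tr, 0.3, 0.32)
        assert depol == pytest.approx(apex, rel=1e-9)
        assert hyper == 0.0
        assert t_peak == pytest.approx(0.008, abs=1e-9)

    def test_window_outside_trace_rejected(self):
        t = np.arange(0, 0.1, 1e-3)
        tr = TimeTrace(t=t, y=np.zeros_like(t), units="V")
        with pytest.raises(ValueError):
            peak_metrics(tr, 0.05, 0.2)

    def test_generator_mean_trace_has_both_transients(self, small_cc_ensemble):
        mean = small_cc_ensemble.group_mean_trace("c10_i105_p20")
        depol, hyper, _ = peak_metrics(mean, 0.1, 0.12)
        assert depol > 0 and hyper < 0


class TestCapacitanceEstimate:
    def test_ideal_step_recovers_capacitance(self):
        tr = gen_capacitance_step(C_m=20e-12)
        est = estimate_capacitance_from_step(tr, 5e-3)
        assert abs(est - 20e-12) / 20e-12 < 0.01

    def test_zero_step_rejected(self):
        tr = gen_capacitance_step()
        with pytest.raises(ValueError):
            estimate_capacitance_from_step(tr, 0.0)

    def test_noisy_steps_median_within_3_percent(self):
        peak = 20e-12 * 5e-3 / 0.5e-3
        errs = []
        for seed in range(100):
            tr = gen_capacitance_step(noise_sd_A=0.01 * peak, seed=seed)
            est = estimate_capacitance_from_step(tr, 5e-3)
            errs.append(abs(est - 20e-12) / 20e-12)
        assert np.median(errs) < 0.03
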