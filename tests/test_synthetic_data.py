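"""Synthetic ensemble and TA-map generators: determinism and closed-loop truth."""

from dataclasses import replace

import numpy as np
import pytest

from photodipole.membrane_circuit import peak_metrics, simulate_current_clamp
from photodipole.synthetic_data import (EnsembleDesign, GroupSpec, GeneratorTruth,
                                        gen_current_clamp_ensemble,
                                        gen_voltage_clamp_ensemble,
                                        gen_ta_fixture, expected_group_response,
                                        _group_drive, HOLDING_POTENTIALS_V)


def _design(groups, seed=0):
    return EnsembleDesign(groups=tuple(groups), seed=seed)


class TestDeterminism:
    def test_current_clamp_bit_reproducible(self, default_truth):
        d = _design([GroupSpec(10.0, 105.0, 20.0, 3)], seed=9)
        e1 = gen_current_clamp_ensemble(d, default_truth)
        e2 = gen_current_clamp_ensemble(d, default_truth)
        for a, b in zip(e1.traces["c10_i105_p20"], e2.traces["c10_i105_p20"]):
            assert np.array_equal(a.y, b.y)

    def test_different_seed_differs(self, default_truth):
        e1 = gen_current_clamp_ensemble(
            _design([GroupSpec(10.0, 105.0, 20.0, 2)], seed=1), default_truth)
        e2 = gen_current_clamp_ensemble(
            _design([GroupSpec(10.0, 105.0, 20.0, 2)], seed=2), default_truth)
        assert not np.array_equal(e1.traces["c10_i105_p20"][0].y,
                                  e2.traces["c10_i105_p20"][0].y)

    def test_ta_map_reproducible(self):
        m1 = gen_ta_fixture("SDS", "us", noise_sd=1e-4, seed=5)
        m2 = gen_ta_fixture("SDS", "us", noise_sd=1e-4, seed=5)
        assert np.array_equal(m1.dTT, m2.dTT)


class TestCurrentClampEnsemble:
    def test_group_amplitude_matches_configured_mean(self, default_truth):
        """Per-cell amplitudes (regressed onto the noiseless reference
        shape, which removes the peak-reading noise bias) average to the
        configured group mean within 2 SEM at n = 50."""
        group = GroupSpec(10.0, 105.0, 20.0, 50)
        design = _design([group], seed=77)
        ens = gen_current_clamp_ensemble(design, default_truth)
        dvs, scale = _group_drive(group, design, default_truth)
        dvs_s = dvs.copy_with(dvs.y * scale, dy_dt=dvs.dy_dt * scale)
        ref = simulate_current_clamp(dvs_s, default_truth.circuit,
                                     design.filter_cutoff_hz)
        shape = ref.y - default_truth.circuit.V_rest
        amps = []
        for tr in ens.traces[group.key]:
            base = tr.y[(tr.t >= 0.05) & (tr.t < 0.1)].mean()
            amps.append(np.dot(shape, tr.y - base) / np.dot(shape, shape))
        amps = np.asarray(amps)
        sem = amps.std(ddof=1) / np.sqrt(amps.size)
        assert abs(amps.mean() - 1.0) < 2 * sem + 1e-3

    def test_amplitude_covaries_with_resting_potential(self, default_truth):
        """Cells resting more negative respond more strongly."""
        group = GroupSpec(10.0, 105.0, 20.0, 60)
        design = _design([group], seed=5)
        quiet = replace(default_truth, noise_sd_mV=0.0, drift_amp_mV=0.0)
        ens = gen_current_clamp_ensemble(design, quiet)
        v_rest, depol = [], []
        for tr in ens.traces[group.key]:
            d, _, _ = peak_metrics(tr, 0.1, 0.12)
            v_rest.append(tr.meta["V_rest_V"])
            depol.append(d)
        slope = np.polynomial.polynomial.polyfit(v_rest, depol, 1)[1]
        assert slope < 0                      # more negative V -> larger depol

    def test_vehicle_group_has_no_light_locked_response(self, default_truth):
        """Vehicle amplitudes regressed on the response shape are zero-mean."""
        groups = [GroupSpec(0.0, 105.0, 20.0, 30), GroupSpec(10.0, 105.0, 20.0, 3)]
        design = _design(groups, seed=21)
        ens = gen_current_clamp_ensemble(design, default_truth)
        dvs, scale = _group_drive(groups[1], design, default_truth)
        dvs_s = dvs.copy_with(dvs.y * scale, dy_dt=dvs.dy_dt * scale)
        ref = simulate_current_clamp(dvs_s, default_truth.circuit,
                                     design.filter_cutoff_hz)
        shape = ref.y - default_truth.circuit.V_rest
        amps = []
        for tr in ens.traces["c0_i105_p20"]:
            base = tr.y[(tr.t >= 0.05) & (tr.t < 0.1)].mean()
            amps.append(np.dot(shape, tr.y - base) / np.dot(shape, shape))
        amps = np.asarray(amps)
        sem = amps.std(ddof=1) / np.sqrt(amps.size)
        assert abs(amps.mean()) < 3 * sem

    def test_expected_means_monotone_in_intensity_and_concentration(
            self, default_truth):
        design = EnsembleDesign.default_hek(n_cells=1)
        means = {g.key: expected_group_response(g, design, default_truth)[0]
                 for g in design.groups}
        for conc in ("c5", "c10"):
            seq = [means[f"{conc}_i{i:g}_p20"] for i in (27, 54, 79, 105)]
            assert all(a < b for a, b in zip(seq, seq[1:]))
        for i in (27, 54, 79, 105):
            assert means[f"c5_i{i:g}_p20"] == pytest.approx(
                0.5 * means[f"c10_i{i:g}_p20"], rel=1e-9)

    def test_anchor_group_mean_is_printed_value(self, default_truth):
        design = EnsembleDesign.default_hek(n_cells=1)
        d, h = expected_group_response(GroupSpec(10.0, 105.0, 20.0, 1),
                                       design, default_truth)
        assert d * 1e3 == pytest.approx(3.0, abs=0.01)
        assert h * 1e3 == pytest.approx(-0.7, abs=0.05)


class TestVoltageClampEnsemble:
    def test_step_family_and_leak_linearity(self, default_truth):
        quiet = replace(default_truth, vc_noise_sd_pA=0.5)
        design = _design([GroupSpec(0.0, 105.0, 20.0, 2)], seed=3)
        ens = gen_voltage_clamp_ensemble(design, quiet)
        sweeps = [tr for tr in ens.traces["c0_i105_p20"]
                  if tr.meta["cell_id"] == 0]
        assert len(sweeps) == len(HOLDING_POTENTIALS_V)
        holds = np.array([tr.meta["V_hold_V"] for tr in sweeps])
        dark = np.array([tr.y[:400].mean() for tr in sweeps])
        slope = np.polynomial.polynomial.polyfit(holds, dark, 1)[1]
        g_leak = 1.0 / quiet.circuit.R_m
        assert slope == pytest.approx(g_leak, rel=0.05)

    def test_light_evoked_peak_grows_with_concentration(self, default_truth):
        quiet = replace(default_truth, vc_noise_sd_pA=0.0)
        peaks = {}
        for conc in (5.0, 10.0):
            design = _design([GroupSpec(conc, 105.0, 20.0, 1)], seed=4)
            ens = gen_voltage_clamp_ensemble(design, quiet)
            key = f"c{conc:g}_i105_p20"
            tr = [s for s in ens.traces[key]
                  if abs(s.meta["V_hold_V"] + 0.060) < 1e-9][0]
            evoked = tr.y - tr.y[:400].mean()
            peaks[conc] = abs(evoked.min())
        assert peaks[10.0] > peaks[5.0]

    def test_reproducible(self, default_truth):
        d = _design([GroupSpec(5.0, 54.0, 20.0, 1)], seed=8)
        e1 = gen_voltage_clamp_ensemble(d, default_truth)
        e2 = gen_voltage_clamp_ensemble(d, default_truth)
        for a, b in zip(e1.traces["c5_i54_p20"], e2.traces["c5_i54_p20"]):
            assert np.array_equal(a.y, b.y)


class TestTAFixtures:
    @pytest.mark.parametrize("medium,center", [("water", 520.0), ("SDS", 500.0)])
    def test_us_band_signs(self, medium, center):
        """GSB band positive at its centre, cis band negative below 400 nm."""
        m = gen_ta_fixture(medium, "us", seed=0)
        early = m.dTT[0]
        assert early[np.argmin(np.abs(m.wavelengths - center))] > 0
        assert early[np.argmin(np.abs(m.wavelengths - 370.0))] < 0

    def test_ps_regime_has_fast_component_and_plateau(self):
        m = gen_ta_fixture("water", "ps", seed=0)
        gsb_idx = np.argmin(np.abs(m.wavelengths - m.meta["gsb_center_nm"]))
        kin = m.dTT[:, gsb_idx]
        assert kin[0] > kin[-1] > 0.2 * kin[0]   # decays onto a plateau

    def test_invalid_medium_rejected(self):
        with pytest.raises(ValueError):
            gen_ta_fixture("hexane", "us")
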