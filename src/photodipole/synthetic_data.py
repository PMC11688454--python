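"""Seeded synthetic-data generators with recorded ground truth.

The raw recordings behind the analysis (whole-cell patch-clamp traces and
transient-absorption maps) are not distributed, so every analysis stage
is exercised on synthetic ensembles generated here.  The generators
realise the statistical structure the analysis assumes -- group means
that follow the photostationary intensity law, per-cell resting-potential
variability with the dipole-asymmetry covariation, acquisition noise and
slow drift, 10 kHz sampling with a 2 kHz low-pass -- and write their
ground truth into the ensemble manifest so closed-loop recovery
(generate -> analyse -> compare to truth) is the testable contract.

These are emulations: they share the model family with the analysis and
do not contain channel noise spectra, electrode artifacts, or real
cell-to-cell kinetic heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from photodipole.photokinetics import (LightProtocol, PhotoswitchParams,
                                       simulate_populations,
                                       photostationary_fractions)
from photodipole.dipole_partition import (MembraneField, orientation_ratio,
                                          excess_and_asymmetry)
from photodipole.membrane_circuit import (MembraneCircuitParams, TimeTrace,
                                          surface_potential_trace,
                                          simulate_current_clamp,
                                          simulate_voltage_clamp,
                                          peak_metrics)
from photodipole.spectrofit import TAMap

__all__ = [
    "GroupSpec",
    "EnsembleDesign",
    "GeneratorTruth",
    "TraceEnsemble",
    "expected_group_response",
    "gen_current_clamp_ensemble",
    "gen_voltage_clamp_ensemble",
    "gen_ta_fixture",
    "gen_capacitance_step",
    "HOLDING_POTENTIALS_V",
]

# voltage-clamp step family: -100..+100 mV in 20 mV steps
HOLDING_POTENTIALS_V = tuple(np.round(np.arange(-100, 101, 20) * 1e-3, 4))

_INTENSITIES = (27.0, 54.0, 79.0, 105.0)


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: loading concentration x light dose."""

    concentration_uM: float    # 0 = vehicle control
    intensity_mWmm2: float
    pulse_ms: float
    n_cells: int

    def __post_init__(self) -> None:
        if self.concentration_uM not in (0.0, 5.0, 10.0):
            raise ValueError("concentration must be 0, 5 or 10 uM")
        if self.intensity_mWmm2 not in _INTENSITIES:
            raise ValueError(f"intensity must be one of {_INTENSITIES}")
        if self.pulse_ms not in (20.0, 200.0):
            raise ValueError("pulse length must be 20 or 200 ms")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def key(self) -> str:
        return f"c{self.concentration_uM:g}_i{self.intensity_mWmm2:g}_p{self.pulse_ms:g}"


@dataclass(frozen=True)
class EnsembleDesign:
    """Group layout and acquisition settings of a synthetic experiment."""

    groups: tuple[GroupSpec, ...]
    sampling_rate_hz: float = 10_000.0
    filter_cutoff_hz: float = 2_000.0
    pre_s: float = 0.100
    post_s: float = 0.400
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design needs at least one group")
        if self.sampling_rate_hz <= 2 * self.filter_cutoff_hz:
            raise ValueError("sampling rate must exceed twice the filter cutoff")
        object.__setattr__(self, "groups", tuple(self.groups))

    @classmethod
    def default_hek(cls, n_cells: int = 20, pulse_ms: float = 20.0,
                    seed: int = 0) -> "EnsembleDesign":
        """Both concentrations at all four intensities, plus vehicle."""
        groups = [GroupSpec(0.0, 105.0, pulse_ms, n_cells)]
        for conc in (5.0, 10.0):
            for inten in _INTENSITIES:
                groups.append(GroupSpec(conc, inten, pulse_ms, n_cells))
        return cls(groups=tuple(groups), seed=seed)


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground-truth configuration the generators realise.

    The surface-potential drive is anchored so the noiseless model
    response at 10 uM / 105 mW mm^-2 peaks exactly at ``base_depol_mV``
    (the measured population mean there); other intensities follow the
    forward model itself (approximately the photostationary cis-fraction
    law), and concentration scales the drive by ``conc_factor`` (0.5 at
    5 uM).  Hyperpolarization follows from the circuit dynamics rather
    than being set independently.
    """

    base_depol_mV: float = 3.0
    conc_factor_5uM: float = 0.5
    v_rest_mean_mV: float = -35.0
    v_rest_sd_mV: float = 8.0
    noise_sd_mV: float = 0.15
    drift_amp_mV: float = 0.3
    drift_hz: float = 1.0
    vc_noise_sd_pA: float = 5.0
    membrane_thickness_m: float = 5e-9
    temperature_K: float = 298.15
    photoswitch: PhotoswitchParams = field(default_factory=PhotoswitchParams)
    circuit: MembraneCircuitParams = field(default_factory=MembraneCircuitParams)

    def conc_factor(self, concentration_uM: float) -> float:
        return {0.0: 0.0, 5.0: self.conc_factor_5uM, 10.0: 1.0}[concentration_uM]

    def intensity_factor(self, intensity: float) -> float:
        """Nominal photostationary intensity law (the model's amplitude
        scaling up to a weak kinetic shape factor)."""
        _, n_ref = photostationary_fractions(105.0, self.photoswitch)
        _, n = photostationary_fractions(intensity, self.photoswitch)
        return n / n_ref

    def asym_at(self, V_rest: float) -> float:
        """Magnitude of the leaflet asymmetry at a resting potential (V)."""
        f = MembraneField.from_potential(V_rest, self.membrane_thickness_m,
                                         self.temperature_K)
        _, a = excess_and_asymmetry(orientation_ratio(self.photoswitch.mu_trans, f))
        return abs(a)

    def to_manifest(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class TraceEnsemble:
    """A set of per-cell traces grouped by experimental condition."""

    design: EnsembleDesign
    truth: GeneratorTruth
    traces: dict        # group key -> list[TimeTrace]
    kind: str           # "current_clamp" | "voltage_clamp"
    t_on: float
    manifest: dict = field(default_factory=dict)

    def group(self, key: str):
        return self.traces[key]

    def group_mean_trace(self, key: str, V_hold: float | None = None) -> TimeTrace:
        """Pointwise mean over cells within a group.

        For voltage-clamp ensembles, ``V_hold`` selects the sweep.
        """
        traces = self.traces[key]
        if V_hold is not None:
            traces = [tr for tr in traces
                      if abs(tr.meta["V_hold_V"] - V_hold) < 1e-9]
            if not traces:
                raise KeyError(f"no sweeps at V_hold={V_hold}")
        y = np.mean([tr.y for tr in traces], axis=0)
        t0 = traces[0]
        return TimeTrace(t=t0.t.copy(), y=y, units=t0.units,
                         meta={**t0.meta, "n_averaged": len(traces)})


def _cell_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _noise_and_drift(rng: np.random.Generator, t: np.ndarray,
                     truth: GeneratorTruth) -> np.ndarray:
    noise = rng.normal(0.0, truth.noise_sd_mV * 1e-3, t.size)
    phase = rng.uniform(0.0, 2 * np.pi)
    drift = truth.drift_amp_mV * 1e-3 * np.sin(2 * np.pi * truth.drift_hz * t + phase)
    return noise + drift


def _anchor_scale(pulse_ms: float, design: EnsembleDesign,
                  truth: GeneratorTruth) -> float:
    """Drive scale anchoring the 10 uM / 105 mW mm^-2 noiseless peak to
    ``base_depol_mV`` for a reference cell at the mean resting potential."""
    proto = LightProtocol.pulse(design.pre_s, pulse_ms * 1e-3, design.post_s, 105.0)
    pop = simulate_populations(proto, truth.photoswitch,
                               dt_out=1.0 / design.sampling_rate_hz)
    asym_ref = truth.asym_at(truth.v_rest_mean_mV * 1e-3)
    dvs = surface_potential_trace(pop, truth.circuit, asym_ref)
    vm = simulate_current_clamp(dvs, truth.circuit, design.filter_cutoff_hz)
    peak, _, _ = peak_metrics(vm, design.pre_s, design.pre_s + pulse_ms * 1e-3)
    return truth.base_depol_mV * 1e-3 / peak


def _group_drive(group: GroupSpec, design: EnsembleDesign, truth: GeneratorTruth):
    """Surface-potential drive and its scaling for one group.

    The drive is the forward model's own (so the data lie exactly in the
    fitted model family); ``scale`` combines the concentration factor
    with the anchor that pins the reference group's peak to the measured
    population mean.
    """
    proto = LightProtocol.pulse(design.pre_s, group.pulse_ms * 1e-3, design.post_s,
                                group.intensity_mWmm2)
    pop = simulate_populations(proto, truth.photoswitch,
                               dt_out=1.0 / design.sampling_rate_hz)
    asym_ref = truth.asym_at(truth.v_rest_mean_mV * 1e-3)
    dvs = surface_potential_trace(pop, truth.circuit, asym_ref)
    cf = truth.conc_factor(group.concentration_uM)
    if cf == 0.0:
        return dvs, 0.0
    return dvs, cf * _anchor_scale(group.pulse_ms, design, truth)


def expected_group_response(group: GroupSpec, design: EnsembleDesign,
                            truth: GeneratorTruth) -> tuple[float, float]:
    """Noiseless reference-cell (depol, hyper) peaks in volts for a group."""
    dvs, scale = _group_drive(group, design, truth)
    if scale == 0.0:
        return 0.0, 0.0
    dvs_s = dvs.copy_with(dvs.y * scale,
                          dy_dt=None if dvs.dy_dt is None else dvs.dy_dt * scale)
    vm = simulate_current_clamp(dvs_s, truth.circuit, design.filter_cutoff_hz)
    d, h, _ = peak_metrics(vm, design.pre_s, design.pre_s + group.pulse_ms * 1e-3)
    return d, h


def gen_current_clamp_ensemble(design: EnsembleDesign,
                               truth: GeneratorTruth | None = None) -> TraceEnsemble:
    """Current-clamp voltage ensemble (one trace per cell per group).

    Per cell: resting potential drawn from the truth distribution
    (truncated to [-90, -10] mV), response amplitude covarying with the
    resting potential through the Boltzmann asymmetry, acquisition noise
    and slow sinusoidal drift added post-filter.  Vehicle groups carry
    noise and drift only.  Bit-reproducible for a fixed design seed.
    """
    truth = truth or GeneratorTruth()
    asym_ref = truth.asym_at(truth.v_rest_mean_mV * 1e-3)
    traces: dict = {}
    group_seeds = np.random.SeedSequence(design.seed).spawn(len(design.groups))
    for group, gseed in zip(design.groups, group_seeds):
        dvs, scale = _group_drive(group, design, truth)
        cell_rngs = [np.random.default_rng(s) for s in gseed.spawn(group.n_cells)]
        out = []
        for i, rng in enumerate(cell_rngs):
            v_rest = np.clip(rng.normal(truth.v_rest_mean_mV, truth.v_rest_sd_mV),
                             -90.0, -10.0) * 1e-3
            cell_scale = scale * truth.asym_at(v_rest) / asym_ref
            circ = replace(truth.circuit, V_rest=v_rest)
            dvs_cell = dvs.copy_with(dvs.y * cell_scale,
                                     dy_dt=None if dvs.dy_dt is None
                                     else dvs.dy_dt * cell_scale)
            vm = simulate_current_clamp(dvs_cell, circ, design.filter_cutoff_hz)
            y = vm.y + _noise_and_drift(rng, vm.t, truth)
            out.append(vm.copy_with(y,
                                    cell_id=i, group=group.key,
                                    concentration_uM=group.concentration_uM,
                                    intensity_mWmm2=group.intensity_mWmm2,
                                    pulse_ms=group.pulse_ms,
                                    V_rest_V=v_rest,
                                    t_on_s=design.pre_s,
                                    t_off_s=design.pre_s + group.pulse_ms * 1e-3,
                                    filter_cutoff_hz=design.filter_cutoff_hz))
        traces[group.key] = out
    expected = {g.key: expected_group_response(g, design, truth)
                for g in design.groups}
    manifest = {"kind": "current_clamp", "seed": design.seed,
                "design": asdict(design),
                "truth": truth.to_manifest(),
                "group_mean_depol_mV": {k: v[0] * 1e3 for k, v in expected.items()},
                "group_mean_hyper_mV": {k: v[1] * 1e3 for k, v in expected.items()}}
    return TraceEnsemble(design=design, truth=truth, traces=traces,
                         kind="current_clamp", t_on=design.pre_s, manifest=manifest)


def gen_voltage_clamp_ensemble(design: EnsembleDesign,
                               truth: GeneratorTruth | None = None) -> TraceEnsemble:
    """Voltage-clamp step-family ensemble.

    Eleven holding potentials (-100..+100 mV, 20 mV steps) per cell, each
    sweep carrying the light pulse; leak current is linear in the holding
    potential with conductance ``1/R_m`` and the light-evoked component
    scales with the group's configured amplitude factor.
    """
    truth = truth or GeneratorTruth()
    traces: dict = {}
    group_seeds = np.random.SeedSequence(design.seed ^ 0x5F5F).spawn(len(design.groups))
    for group, gseed in zip(design.groups, group_seeds):
        dvs, scale = _group_drive(group, design, truth)
        cell_rngs = [np.random.default_rng(s) for s in gseed.spawn(group.n_cells)]
        out = []
        for i, rng in enumerate(cell_rngs):
            cell_scale = scale * rng.normal(1.0, 0.05) if scale else 0.0
            dvs_cell = dvs.copy_with(dvs.y * cell_scale,
                                     dy_dt=None if dvs.dy_dt is None
                                     else dvs.dy_dt * cell_scale)
            for V_hold in HOLDING_POTENTIALS_V:
                iv = simulate_voltage_clamp(dvs_cell, truth.circuit, V_hold,
                                            design.filter_cutoff_hz)
                y = iv.y + rng.normal(0.0, truth.vc_noise_sd_pA * 1e-12, iv.t.size)
                out.append(iv.copy_with(y,
                                        cell_id=i, group=group.key,
                                        concentration_uM=group.concentration_uM,
                                        intensity_mWmm2=group.intensity_mWmm2,
                                        pulse_ms=group.pulse_ms,
                                        V_hold_V=V_hold,
                                        t_on_s=design.pre_s,
                                        t_off_s=design.pre_s + group.pulse_ms * 1e-3))
        traces[group.key] = out
    manifest = {"kind": "voltage_clamp", "seed": design.seed,
                "design": asdict(design),
                "truth": truth.to_manifest(),
                "leak_conductance_S": 1.0 / truth.circuit.R_m}
    return TraceEnsemble(design=design, truth=truth, traces=traces,
                         kind="voltage_clamp", t_on=design.pre_s, manifest=manifest)


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def gen_ta_fixture(medium: str = "water", regime: str = "us",
                   noise_sd: float = 0.0, seed: int | None = 0) -> TAMap:
    """Synthetic transient-absorption map with known injected kinetics.

    Microsecond regime: a positive ground-state-bleach band (520 nm in
    water, 500 nm in SDS) and a negative cis-absorption band below
    400 nm, both decaying mono-exponentially with the medium's cis
    lifetime (42 us water, 300 us SDS).  Picosecond regime: GSB kinetics
    = fast isomerisation component (2.7 ps water / 2.2 ps SDS) plus a
    long-lived plateau, and a fast negative photoinduced-absorption band
    at 620 nm.  Injected parameters are recorded in ``meta`` for
    closed-loop recovery tests.
    """
    if medium not in ("water", "SDS"):
        raise ValueError("medium must be 'water' or 'SDS'")
    if regime not in ("ps", "us"):
        raise ValueError("regime must be 'ps' or 'us'")
    rng = np.random.default_rng(seed)
    wl = np.arange(340.0, 651.0, 2.0)
    gsb_center = 520.0 if medium == "water" else 500.0

    if regime == "us":
        tau = 42e-6 if medium == "water" else 300e-6
        delays = np.linspace(2e-6, 8 * tau, 160)
        kin = np.exp(-delays / tau)
        gsb = 1.0e-3 * _gauss(wl, gsb_center, 25.0)
        cis = -0.6e-3 * _gauss(wl, 370.0, 20.0)
        dTT = kin[:, None] * (gsb + cis)[None, :]
        meta = {"medium": medium, "regime": regime, "tau_s": tau,
                "gsb_center_nm": gsb_center, "gsb_amp": 1.0e-3,
                "cis_center_nm": 370.0, "cis_amp": -0.6e-3,
                "noise_sd": noise_sd, "seed": seed}
    else:
        tau_iso = 2.7e-12 if medium == "water" else 2.2e-12
        plateau = 0.25 if medium == "water" else 0.40
        delays = np.linspace(0.2e-12, 20e-12, 120)
        kin = (1 - plateau) * np.exp(-delays / tau_iso) + plateau
        gsb = 1.0e-3 * _gauss(wl, gsb_center, 25.0)
        pia = -0.8e-3 * _gauss(wl, 620.0, 30.0)
        dTT = kin[:, None] * gsb[None, :] + \
            np.exp(-delays / tau_iso)[:, None] * pia[None, :]
        meta = {"medium": medium, "regime": regime, "tau_iso_s": tau_iso,
                "plateau": plateau, "gsb_center_nm": gsb_center,
                "pia_center_nm": 620.0, "noise_sd": noise_sd, "seed": seed}
    if noise_sd > 0:
        dTT = dTT + rng.normal(0.0, noise_sd, dTT.shape)
    return TAMap(wavelengths=wl, delays=delays, dTT=dTT, meta=meta)


def gen_capacitance_step(C_m: float = 20e-12, R_m: float = 500e6,
                         dV_step: float = 5e-3, tau_clamp: float = 0.5e-3,
                         duration: float = 0.05, dt: float = 1e-5,
                         t_step: float = 0.005,
                         noise_sd_A: float = 0.0,
                         seed: int | None = None) -> TimeTrace:
    """Idealised capacitance-test current: exponential transient + leak.

    The transient carries exactly ``C_m * dV_step`` of charge (amplitude
    ``C_m dV / tau_clamp``, decay ``tau_clamp``) on top of the steady leak
    ``dV / R_m``, emulating the 5 mV capacitance-test step.
    """
    t = np.arange(0.0, duration, dt)
    y = np.full_like(t, 0.0)
    after = t >= t_step
    y[after] = (C_m * dV_step / tau_clamp) * np.exp(-(t[after] - t_step) / tau_clamp) \
        + dV_step / R_m
    if noise_sd_A > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd_A, t.size)
    return TimeTrace(t=t, y=y, units="A",
                     meta={"t_step_s": t_step, "dV_step_V": dV_step,
                           "C_true_F": C_m, "R_m_Ohm": R_m})
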