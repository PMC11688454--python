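"""End-to-end driver: generate -> calibrate -> simulate -> report.

All randomness descends from a single seed through
``numpy.random.SeedSequence`` spawning (one child per stage); the report
records every derived seed.  Any stage failure aborts with the stage name
attached.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from photodipole import dipole_partition as dp
from photodipole._pso import PSOConfig
from photodipole.calibration import (calibrate_model, simulate_calibrated_pulse,
                                     intensity_response_curve)
from photodipole.membrane_circuit import peak_metrics
from photodipole.synthetic_data import (EnsembleDesign, GeneratorTruth,
                                        gen_current_clamp_ensemble)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

INTENSITIES = (27.0, 54.0, 79.0, 105.0)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str | None = None
    n_cells: int = 20
    pulse_ms: float = 20.0
    target_intensity: float = 105.0
    target_concentration_uM: float = 10.0
    pso_swarm: int = 40
    pso_iters: int = 250
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a nonnegative integer")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    # keep derived seeds below 2**31 so they survive any int casting downstream
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis chain and return (and optionally write) the report.

    The report carries the desk-check constants (Boltzmann orientation
    ratio, dipole change in SI units), the closed-loop peak depolarization
    and post-pulse hyperpolarization of the calibrated model at the target
    condition, the calibration parameters, the intensity-response curves,
    invariant checks, and all seeds used.
    """
    t_start = time.time()
    seeds = _stage_seeds(config.seed)
    report: dict = {"seed": config.seed,
                    "stage_seeds": {"gen_data": seeds[0], "calibrate": seeds[1]},
                    "config": {"n_cells": config.n_cells,
                               "pulse_ms": config.pulse_ms}}

    try:
        field = dp.MembraneField(E=1e7, T=298.15)
        ratio = dp.orientation_ratio(12.4, field)
        excess, asym = dp.excess_and_asymmetry(ratio)
        dmu_cm = dp.debye_to_coulomb_meter(12.4 - 8.6)
        report["constants"] = {
            "orientation_ratio_trans_1e7Vm_298K": ratio,
            "excess_fraction": excess,
            "normalized_asymmetry": asym,
            "dipole_change_Cm": dmu_cm,
        }
    except Exception as exc:
        raise PipelineError("constants", exc)

    try:
        design = EnsembleDesign.default_hek(n_cells=config.n_cells,
                                            pulse_ms=config.pulse_ms,
                                            seed=seeds[0])
        truth = GeneratorTruth()
        ensemble = gen_current_clamp_ensemble(design, truth)
        group_peaks = {}
        for g in design.groups:
            mean = ensemble.group_mean_trace(g.key)
            d, h, tp = peak_metrics(mean, design.pre_s,
                                    design.pre_s + g.pulse_ms * 1e-3)
            group_peaks[g.key] = {"depol_mV": d * 1e3, "hyper_mV": h * 1e3,
                                  "t_to_peak_ms": tp * 1e3}
        report["ensemble_group_peaks"] = group_peaks
    except Exception as exc:
        raise PipelineError("gen-data", exc)

    try:
        cfg = PSOConfig(swarm=config.pso_swarm, iters=config.pso_iters,
                        seed=seeds[1], patience=60)
        cal = calibrate_model(ensemble, optimizer_config=cfg, seed=seeds[1])
        report["calibration"] = cal.to_dict()
    except Exception as exc:
        raise PipelineError("calibrate", exc)

    try:
        vm, (depol, hyper, t_peak) = simulate_calibrated_pulse(
            cal.model, config.target_intensity, config.pulse_ms,
            config.target_concentration_uM)
        dep_curve, hyp_curve = intensity_response_curve(
            cal.model, INTENSITIES, pulse_ms=config.pulse_ms,
            concentration_uM=config.target_concentration_uM)
        report["model_prediction"] = {
            "intensity_mWmm2": config.target_intensity,
            "concentration_uM": config.target_concentration_uM,
            "peak_depolarization_mV": depol * 1e3,
            "post_pulse_hyperpolarization_mV": hyper * 1e3,
            "time_to_peak_ms": t_peak * 1e3,
            "intensity_response": {
                "intensities_mWmm2": list(INTENSITIES),
                "depol_mV": (dep_curve * 1e3).tolist(),
                "hyper_mV": (hyp_curve * 1e3).tolist(),
            },
        }
    except Exception as exc:
        raise PipelineError("simulate", exc)

    try:
        checks = _invariant_checks(ensemble, dep_curve, hyp_curve)
        report["invariant_checks"] = checks
        report["runtime_s"] = time.time() - t_start
        if config.out_dir is not None:
            from photodipole.io import write_json
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_json(report, out / "report.json")
    except Exception as exc:
        raise PipelineError("report", exc)
    return report


def _invariant_checks(ensemble, dep_curve, hyp_curve) -> dict:
    from photodipole.photokinetics import (LightProtocol, simulate_populations)
    pop = simulate_populations(LightProtocol.pulse(0.01, 0.02, 0.05, 105.0),
                               ensemble.truth.photoswitch, dt_out=1e-5)
    conservation = float(np.max(np.abs(pop.n_trans + pop.n_cis - 1.0)))
    mono_dep = bool(np.all(np.diff(dep_curve) >= -1e-12))
    mono_hyp = bool(np.all(np.diff(-hyp_curve) >= -1e-12))
    return {
        "population_conservation_max_drift": conservation,
        "population_conservation_ok": conservation <= 1e-9,
        "intensity_response_monotone_depol": mono_dep,
        "intensity_response_monotone_hyper": mono_hyp,
    }
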