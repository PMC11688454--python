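"""Equivalent-circuit membrane model driven by a surface potential.

The cell membrane is a parallel RC (capacitance ``C_m``, resistance
``R_m``) resting at ``V_rest``.  Photoisomerisation of the membrane-
embedded dipoles changes the surface potential ``V_s`` at the inner
interface; assuming the change is proportional to the cis fraction,

    dV_s(t) = alpha * asym * n_cis(t),

where ``alpha`` (volts) is the surface-potential change per unit cis
fraction per unit leaflet asymmetry and ``asym`` the Boltzmann leaflet
asymmetry.  ``V_s`` couples to the membrane node through a hybrid element:
a coupling capacitance ``C_s`` (the fast displacement-charge pathway,
responsible for the sharp on/off transients and the post-pulse rebound)
in parallel with a coupling conductance ``G_s`` (the sustained pathway,
responsible for the plateau during long pulses).  In current clamp the
membrane deviation obeys

    C_m * d(dV_m)/dt = -dV_m / R_m + C_s * d(dV_s)/dt + G_s * dV_s

and in voltage clamp the light-evoked current is

    I(t) = -(C_s * d(dV_s)/dt + G_s * dV_s) + (V_hold - V_rest)/R_m,

inward currents negative, depolarizations positive.

Numerics: the current-clamp ODE is integrated with an exact discrete
update of the transformed state ``w = dV_m - (C_s/C_m) dV_s`` under a
zero-order-hold reading of the sampled drive (``dV_s`` constant between
samples).  The update is a first-order linear recurrence evaluated with
``scipy.signal.lfilter``; it is unconditionally stable, exact for step
drives, and O(dt) accurate for smooth drives (dt = 0.1 ms at the 10 kHz
acquisition rate against millisecond kinetics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from photodipole.photokinetics import PopulationTrace

__all__ = [
    "MembraneCircuitParams",
    "TimeTrace",
    "surface_potential_trace",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "peak_metrics",
    "estimate_capacitance_from_step",
    "bessel_lowpass",
]


@dataclass(frozen=True)
class MembraneCircuitParams:
    """Circuit elements of the membrane + surface-potential coupling.

    Defaults are HEK293T-like (C_m = 20 pF, R_m = 500 MOhm, so
    tau_m = 10 ms) with coupling elements calibrated so the default
    photoswitch kinetics reproduce the measured population-mean transient
    amplitudes at the highest light dose (see docs/methods.md).
    """

    C_m: float = 20e-12       # F
    R_m: float = 500e6        # Ohm
    V_rest: float = -35e-3    # V
    C_s: float = 9.58e-12     # F
    G_s: float = 0.614e-9     # S
    alpha: float = 0.3        # V per (cis fraction * asymmetry)

    def __post_init__(self) -> None:
        if self.C_m <= 0 or self.R_m <= 0:
            raise ValueError("C_m and R_m must be > 0")
        if self.C_s < 0 or self.G_s < 0:
            raise ValueError("C_s and G_s must be >= 0")

    @property
    def tau_m(self) -> float:
        return self.R_m * self.C_m


@dataclass
class TimeTrace:
    """Uniformly sampled voltage or current record.

    ``units`` is ``"V"`` or ``"A"``; ``dy_dt`` optionally carries an
    analytic time derivative of ``y`` (same grid) when one is known.
    """

    t: np.ndarray
    y: np.ndarray
    units: str
    meta: dict = field(default_factory=dict)
    dy_dt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise ValueError("trace needs at least two samples")
        if self.units not in ("V", "A"):
            raise ValueError(f"units must be 'V' or 'A', got {self.units!r}")
        steps = np.diff(self.t)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-15):
            raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("trace contains non-finite samples")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def copy_with(self, y: np.ndarray, units: str | None = None,
                  dy_dt: np.ndarray | None = None, **meta) -> "TimeTrace":
        m = dict(self.meta)
        m.update(meta)
        return TimeTrace(t=self.t.copy(), y=np.asarray(y, dtype=float),
                         units=units or self.units, meta=m, dy_dt=dy_dt)


def surface_potential_trace(pop: PopulationTrace, circuit: MembraneCircuitParams,
                            asym: float) -> TimeTrace:
    """Surface-potential change dV_s(t) = alpha * asym * n_cis(t).

    The analytic derivative is propagated from the population trace when
    available, so downstream capacitive currents need no finite
    differencing.
    """
    if abs(asym) > 1:
        raise ValueError("asymmetry must lie in [-1, 1]")
    gain = circuit.alpha * asym
    dy_dt = gain * pop.dn_cis_dt if pop.dn_cis_dt is not None else None
    return TimeTrace(t=pop.t, y=gain * pop.n_cis, units="V",
                     meta={**pop.meta, "kind": "surface_potential"}, dy_dt=dy_dt)


def _cc_response(dVs: np.ndarray, dt: float, circuit: MembraneCircuitParams) -> np.ndarray:
    """Membrane deviation dV_m for a sampled (zero-order-hold) dV_s drive."""
    tau = circuit.tau_m
    ratio = circuit.C_s / circuit.C_m
    c = (circuit.G_s - circuit.C_s / (circuit.R_m * circuit.C_m)) / circuit.C_m
    E = np.exp(-dt / tau)
    b = np.array([0.0, c * tau * (1.0 - E)])
    a = np.array([1.0, -E])
    # start in steady state with the drive held at its first sample
    w0 = c * tau * dVs[0]
    zi = signal.lfiltic(b, a, [w0], [dVs[0]])
    w, _ = signal.lfilter(b, a, dVs, zi=zi)
    return w + ratio * dVs


def simulate_current_clamp(dVs: TimeTrace, circuit: MembraneCircuitParams,
                           filter_cutoff_hz: float | None = None) -> TimeTrace:
    """Membrane-voltage response V_rest + dV_m to a surface-potential drive.

    Linear and time-invariant: responses to superposed drives add.  After
    the drive returns to zero, dV_m relaxes to zero with tau_m.  An
    optional 4-pole Bessel low-pass emulates the acquisition filter.
    """
    if dVs.units != "V":
        raise ValueError("surface-potential drive must be in volts")
    dVm = _cc_response(dVs.y, dVs.dt, circuit)
    y = circuit.V_rest + dVm
    if filter_cutoff_hz is not None:
        y = circuit.V_rest + bessel_lowpass_array(dVm, dVs.dt, filter_cutoff_hz)
    return dVs.copy_with(y, units="V", kind="current_clamp",
                         V_rest_V=circuit.V_rest)


def simulate_voltage_clamp(dVs: TimeTrace, circuit: MembraneCircuitParams,
                           V_hold: float, filter_cutoff_hz: float | None = None) -> TimeTrace:
    """Whole-cell current under voltage clamp at ``V_hold``.

    The light-evoked component is ``-(C_s d(dV_s)/dt + G_s dV_s)``
    (inward negative for a depolarizing surface-potential rise); the leak
    ``(V_hold - V_rest)/R_m`` adds a holding-potential-dependent offset.
    Uses the analytic drive derivative when the trace carries one,
    otherwise a second-order finite difference.
    """
    if dVs.units != "V":
        raise ValueError("surface-potential drive must be in volts")
    dvs_dt = dVs.dy_dt if dVs.dy_dt is not None else np.gradient(dVs.y, dVs.dt)
    evoked = -(circuit.C_s * dvs_dt + circuit.G_s * dVs.y)
    leak = (V_hold - circuit.V_rest) / circuit.R_m
    y = evoked + leak
    if filter_cutoff_hz is not None:
        y = leak + bessel_lowpass_array(evoked, dVs.dt, filter_cutoff_hz)
    return dVs.copy_with(y, units="A", kind="voltage_clamp",
                         V_hold_V=V_hold)


def light_evoked_current(trace: TimeTrace, circuit: MembraneCircuitParams,
                         V_hold: float) -> np.ndarray:
    """Leak-subtracted (light-evoked) component of a voltage-clamp trace."""
    return trace.y - (V_hold - circuit.V_rest) / circuit.R_m


def peak_metrics(trace: TimeTrace, t_on: float, t_off: float,
                 baseline_window_s: float = 0.050,
                 response_window_s: float = 0.300) -> tuple[float, float, float]:
    """Depolarization / hyperpolarization peaks relative to baseline.

    Baseline is the mean over the ``baseline_window_s`` preceding light
    onset.  The depolarization peak is ``max(y - baseline)`` within
    ``response_window_s`` after ``t_on``; the hyperpolarization peak is
    the signed ``min(y - baseline)`` within the same window after
    ``t_off``.  Returns ``(depol_peak, hyper_peak, t_to_peak)`` with
    ``t_to_peak`` measured from light onset.
    """
    if not (trace.t[0] <= t_on < t_off <= trace.t[-1]):
        raise ValueError("light window must lie within the trace span")
    t = trace.t
    base_mask = (t >= t_on - baseline_window_s) & (t < t_on)
    if not base_mask.any():
        raise ValueError("no samples in the baseline window")
    baseline = float(trace.y[base_mask].mean())
    dev = trace.y - baseline

    on_mask = (t >= t_on) & (t <= t_on + response_window_s)
    off_mask = (t >= t_off) & (t <= t_off + response_window_s)
    if not on_mask.any() or not off_mask.any():
        raise ValueError("response window outside the trace")
    depol = float(dev[on_mask].max())
    hyper = float(dev[off_mask].min())
    t_peak = float(t[on_mask][np.argmax(dev[on_mask])] - t_on)
    if depol <= 0.0:          # flat (or purely negative) trace: no peak
        depol = max(depol, 0.0)
        t_peak = 0.0
    hyper = min(hyper, 0.0)
    return depol, hyper, t_peak


def estimate_capacitance_from_step(current: TimeTrace, dV_step: float,
                                   t_step: float | None = None) -> float:
    """Membrane capacitance from the charge of a voltage-step transient.

    ``C = dQ / dV_step`` with ``dQ`` the time integral of the
    leak-subtracted capacitive transient.  The steady leak level is the
    mean over the final 20% of the trace (well past the transient); the
    transient is integrated by the trapezoid rule from the step onset
    (``t_step``, or the trace's ``meta['t_step_s']``) to the end.
    """
    if dV_step == 0:
        raise ValueError("dV_step must be nonzero")
    if t_step is None:
        t_step = current.meta.get("t_step_s")
    if t_step is None:
        raise ValueError("step onset not given and not present in metadata")
    t = current.t
    tail = current.y[t >= t[0] + 0.8 * (t[-1] - t[0])]
    leak = float(tail.mean())
    mask = t >= t_step
    dQ = float(np.trapezoid(current.y[mask] - leak, t[mask]))
    return dQ / dV_step


def bessel_lowpass_array(y: np.ndarray, dt: float, cutoff_hz: float,
                         order: int = 4) -> np.ndarray:
    """Causal 4-pole Bessel low-pass, the standard patch-clamp output filter."""
    sos = signal.bessel(order, cutoff_hz, fs=1.0 / dt, output="sos", norm="mag")
    # prime the filter with the initial level so a nonzero baseline does not ring
    zi = signal.sosfilt_zi(sos) * y[0]
    out, _ = signal.sosfilt(sos, y, zi=zi)
    return out


def bessel_lowpass(trace: TimeTrace, cutoff_hz: float, order: int = 4) -> TimeTrace:
    """Filtered copy of a trace (see :func:`bessel_lowpass_array`)."""
    return trace.copy_with(bessel_lowpass_array(trace.y, trace.dt, cutoff_hz, order),
                           filter_cutoff_hz=cutoff_hz)
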