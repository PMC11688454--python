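"""Two-state trans/cis photoswitch population dynamics.

A push-pull azobenzene in solution or membrane is modelled as a two-state
system: the thermodynamically stable *trans* isomer and the metastable
*cis* isomer.  Under continuous-wave illumination of intensity ``I`` (in
mW mm^-2, the unit the experiments are dosed in) the populations obey

    dn_cis/dt = kappa_TC * I * n_trans - (kappa_CT * I + gamma) * n_cis

with ``n_trans + n_cis = 1``.  ``kappa_TC`` and ``kappa_CT`` are the
light-driven trans->cis and cis->trans rates per unit intensity and
``gamma = 1/tau_cis`` is the thermal cis->trans back-relaxation rate.
The sub-10-ps isomerisation event itself is treated as instantaneous at
these timescales; only population transfer is resolved.

Illumination is piecewise constant (:class:`LightProtocol`), for which the
rate equation has an exact per-segment solution

    n_cis(t) = n_ss + (n0 - n_ss) * exp(-k_tot * t),
    k_tot = (kappa_TC + kappa_CT) * I + gamma,

used as the primary propagator; no step-size error is incurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LightProtocol",
    "PhotoswitchParams",
    "PopulationTrace",
    "photostationary_fractions",
    "simulate_populations",
    "pl_quantum_yield",
    "relative_pl_amplitude",
]


@dataclass(frozen=True)
class LightProtocol:
    """Piecewise-constant illumination protocol.

    Parameters
    ----------
    segments
        Ordered ``(duration_s, intensity_mWmm2)`` pairs.  Segments are
        contiguous: each starts where the previous one ends.
    wavelength_nm
        Excitation wavelength, metadata only (the rates already absorb the
        action spectrum at the working wavelength).
    """

    segments: tuple[tuple[float, float], ...]
    wavelength_nm: float = 470.0

    def __post_init__(self) -> None:
        segs = tuple((float(d), float(i)) for d, i in self.segments)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        for d, i in segs:
            if d <= 0:
                raise ValueError(f"segment duration must be > 0, got {d}")
            if i < 0:
                raise ValueError(f"intensity must be >= 0, got {i}")
        object.__setattr__(self, "segments", segs)

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _ in self.segments))

    @property
    def boundaries(self) -> np.ndarray:
        """Segment start/end times, length ``len(segments) + 1``."""
        return np.concatenate([[0.0], np.cumsum([d for d, _ in self.segments])])

    def intensity_at(self, t: np.ndarray) -> np.ndarray:
        """Intensity sampled at times ``t`` (right-open segments)."""
        t = np.asarray(t, dtype=float)
        edges = self.boundaries
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(self.segments) - 1)
        vals = np.array([i for _, i in self.segments])
        return vals[idx]

    @classmethod
    def pulse(cls, pre_s: float, pulse_s: float, post_s: float,
              intensity: float, wavelength_nm: float = 470.0) -> "LightProtocol":
        """Dark / light / dark three-segment stimulus (the patch-clamp protocol)."""
        return cls(((pre_s, 0.0), (pulse_s, intensity), (post_s, 0.0)),
                   wavelength_nm=wavelength_nm)


@dataclass(frozen=True)
class PhotoswitchParams:
    """Kinetic and photophysical constants of the photoswitch.

    Attributes
    ----------
    kappa_TC, kappa_CT
        Light-driven trans->cis / cis->trans rates, s^-1 per (mW mm^-2).
    gamma
        Thermal cis->trans relaxation rate, s^-1 (``1/tau_cis``).
    mu_trans, mu_cis
        Permanent dipole moments of the two isomers, debye.
    k_R, k_NR
        Radiative / non-radiative excited-state decay rates, s^-1.
    """

    kappa_TC: float = 5.0
    kappa_CT: float = 1.0
    gamma: float = 1000.0           # default membrane tau_cis = 1 ms
    mu_trans: float = 12.4
    mu_cis: float = 8.6
    k_R: float = 1e8
    k_NR: float = 9e8

    def __post_init__(self) -> None:
        for name in ("kappa_TC", "kappa_CT", "gamma", "mu_trans", "mu_cis", "k_R", "k_NR"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gamma == 0 and self.kappa_CT == 0 and self.kappa_TC == 0:
            raise ValueError("all rates zero: no dynamics defined")


@dataclass
class PopulationTrace:
    """Uniformly sampled trans/cis population fractions.

    ``dn_cis_dt`` is the rate-equation right-hand side evaluated at the
    samples (exact, not a finite difference); downstream circuit code uses
    it for the capacitive displacement current.
    """

    t: np.ndarray
    n_trans: np.ndarray
    n_cis: np.ndarray
    dn_cis_dt: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.n_trans = np.asarray(self.n_trans, dtype=float)
        self.n_cis = np.asarray(self.n_cis, dtype=float)
        if not (self.t.shape == self.n_trans.shape == self.n_cis.shape):
            raise ValueError("t, n_trans, n_cis must have identical shapes")
        if np.max(np.abs(self.n_trans + self.n_cis - 1.0)) > 1e-9:
            raise ValueError("population fractions must sum to 1 within 1e-9")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def photostationary_fractions(I0: float, params: PhotoswitchParams) -> tuple[float, float]:
    """Steady-state ``(n_trans, n_cis)`` under constant illumination ``I0``.

    At the photostationary state the trans fraction satisfies
    ``n_trans = ((kappa_CT I0 + gamma) / (kappa_TC I0)) * n_cis`` with the
    pair normalised to 1, i.e.::

        n_cis,ss = kappa_TC I0 / ((kappa_TC + kappa_CT) I0 + gamma)

    ``I0 = 0`` (or ``kappa_TC = 0``) returns the dark state ``(1, 0)``:
    thermal relaxation drains everything back to trans.
    """
    if I0 < 0:
        raise ValueError(f"intensity must be >= 0, got {I0}")
    pump = params.kappa_TC * I0
    drain = params.kappa_CT * I0 + params.gamma
    if pump == 0.0:
        return (1.0, 0.0)
    if drain == 0.0:           # gamma = 0, kappa_CT = 0: everything pumped to cis
        return (0.0, 1.0)
    n_cis = pump / (pump + drain)
    return (1.0 - n_cis, n_cis)


def _segment_rates(I: float, params: PhotoswitchParams) -> tuple[float, float]:
    """(n_cis steady state, total relaxation rate) within one constant-I segment."""
    pump = params.kappa_TC * I
    k_tot = (params.kappa_TC + params.kappa_CT) * I + params.gamma
    n_ss = pump / k_tot if k_tot > 0 else 0.0
    return n_ss, k_tot


def simulate_populations(protocol: LightProtocol, params: PhotoswitchParams,
                         n_cis_init: float = 0.0, dt_out: float = 1e-4) -> PopulationTrace:
    """Propagate the two-state populations through an illumination protocol.

    Uses the exact per-segment solution of the linear rate equation, so the
    result is analytic at every output sample regardless of ``dt_out``.

    Parameters
    ----------
    protocol
        Piecewise-constant light protocol.
    params
        Kinetic constants.
    n_cis_init
        Initial cis fraction in [0, 1]; default 0 (dark-adapted, all trans).
    dt_out
        Output sampling interval, s.
    """
    if not 0.0 <= n_cis_init <= 1.0:
        raise ValueError("n_cis_init must lie in [0, 1]")
    if dt_out <= 0:
        raise ValueError("dt_out must be > 0")

    n_steps = int(np.floor(protocol.total_duration / dt_out + 1e-9))
    t = np.arange(n_steps + 1) * dt_out
    n_cis = np.empty_like(t)
    dn = np.empty_like(t)
    edges = protocol.boundaries

    n0 = float(n_cis_init)
    for k, (dur, I) in enumerate(protocol.segments):
        t0, t1 = edges[k], edges[k + 1]
        last = k == len(protocol.segments) - 1
        mask = (t >= t0) if last else ((t >= t0) & (t < t1))
        n_ss, k_tot = _segment_rates(I, params)
        tau_local = t[mask] - t0
        if k_tot > 0:
            n_cis[mask] = n_ss + (n0 - n_ss) * np.exp(-k_tot * tau_local)
            n0 = n_ss + (n0 - n_ss) * np.exp(-k_tot * dur)
        else:
            n_cis[mask] = n0
        dn[mask] = params.kappa_TC * I * (1.0 - n_cis[mask]) - \
            (params.kappa_CT * I + params.gamma) * n_cis[mask]

    n_cis = np.clip(n_cis, 0.0, 1.0)
    return PopulationTrace(t=t, n_trans=1.0 - n_cis, n_cis=n_cis, dn_cis_dt=dn,
                           meta={"wavelength_nm": protocol.wavelength_nm,
                                 "dt_out_s": dt_out})


def pl_quantum_yield(k_R: float, k_NR: float) -> float:
    """Photoluminescence quantum yield eta = k_R / (k_R + k_NR)."""
    if k_R < 0 or k_NR < 0:
        raise ValueError("decay rates must be >= 0")
    if k_R + k_NR == 0:
        raise ValueError("k_R + k_NR must be > 0")
    return k_R / (k_R + k_NR)


def relative_pl_amplitude(I0: float, params: PhotoswitchParams) -> float:
    """Relative steady-state PL amplitude, arbitrary units.

    Emission comes only from the trans isomer, so the amplitude is the
    product of the emitting steady-state trans fraction and the quantum
    yield: ``n_trans,ss(I0) * eta``.  Both intensity-dependent trans
    depletion (isomerisation sweeps population into cis) and internal
    conversion (k_NR) therefore quench it.
    """
    n_trans, _ = photostationary_fractions(I0, params)
    return n_trans * pl_quantum_yield(params.k_R, params.k_NR)
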