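# Methods

`photodipole` models how a membrane-embedded push–pull azobenzene
photoswitch modulates the membrane potential of a cell when illuminated,
and implements the spectroscopic and electrophysiological analysis
chain around that model: decay fitting for the photophysics, synthetic
patch-clamp data generation, and calibration of the coupled model
against trace ensembles.

## Photoswitch population kinetics

The switch is a two-state system — stable *trans*, metastable *cis* —
with populations `n_trans + n_cis = 1` obeying

    dn_cis/dt = kappa_TC * I * n_trans − (kappa_CT * I + gamma) * n_cis

where `I` is the illumination intensity in mW mm⁻² (the unit the
experiments are dosed in; photon-flux bookkeeping is deliberately
avoided — rates per unit intensity absorb the cross-section at the
working wavelength), `kappa_TC`, `kappa_CT` are the light-driven rates
per unit intensity, and `gamma = 1/tau_cis` is the thermal cis→trans
relaxation rate.  The sub-10-ps isomerisation event is treated as
instantaneous: only population transfer matters at circuit timescales.

Illumination is piecewise constant, so each segment has the exact
solution `n_cis(t) = n_ss + (n0 − n_ss) exp(−k_tot t)` with
`k_tot = (kappa_TC + kappa_CT) I + gamma`; this closed form is the
production propagator (no step-size error; a fixed-step RK4 integrator
exists only as a test oracle).  The photostationary state is
`n_cis,ss = kappa_TC I / k_tot`.  Steady-state photoluminescence is
`n_trans,ss × eta` with quantum yield `eta = k_R/(k_R + k_NR)`.

Defaults: `kappa_TC = 5`, `kappa_CT = 1` s⁻¹ per mW mm⁻² and
`gamma = 1000` s⁻¹ (`tau_cis = 1 ms`).  The membrane-phase cis lifetime
is not measured — only water (42 µs) and SDS micelles (300 µs) are — so
1 ms is a deliberate choice between the micellar value and the slower
relaxation expected in the less polar bilayer interior; the kappa
values were chosen so that the photostationary cis fraction still rises
visibly across the experimental 27–105 mW mm⁻² range
(`n_cis,ss` = 0.12 → 0.32), matching the observed dose dependence of the
photoresponse.  All three are overridable and are re-fitted by the
calibration stage anyway.

## Boltzmann dipole partitioning

A molecule with permanent dipole `mu` in the transmembrane field `E`
has orientation energies differing by `dU = 2 mu E`, giving

    N_parallel / N_antiparallel = exp(2 mu E / kB T)

Evaluated at the trans dipole 12.4 D (DFT), `E ≈ 1e7 V m⁻¹` and 298.15 K
this is 1.223 — a ~22–25% excess of field-aligned molecules, i.e. an
uneven leaflet occupancy.  The normalised asymmetry
`(r − 1)/(r + 1) = tanh(mu E / kB T)` is the factor scaling the
photoresponse; because `tanh` is nearly linear over physiological
fields, the predicted photo-depolarization amplitude is linear in the
resting potential (deviation < 0.5% of full scale over [−100, 0] mV),
matching the measured amplitude/V_rest correlation.  The dipole change
on isomerisation, `Δmu = (12.4 − 8.6) D = 1.27e−29 C m`, sets the
relative magnitude of the light-induced surface-charge change.

Flip-flop between leaflets is a reduced two-state master equation with
detailed balance `k_oi / k_io = exp(2 mu E / kB T)`; rates are split
symmetrically (`k_oi = base_rate √r`).  The absolute `base_rate`
(default 1 s⁻¹) is not transferable from coarse-grained simulation —
only occupancy ratios are treated as quantitative.  A deterministic
(exact linear-ODE) and a Gillespie mode are provided.  Sign
conventions: voltages are depolarization-positive; only magnitudes and
monotonicities of the signed field quantities are interpreted.

## Equivalent-circuit membrane model

The membrane is a parallel RC (`C_m = 20 pF`, `R_m = 500 MΩ`,
`tau_m = 10 ms`, HEK-like; `V_rest = −35 mV`) driven by a
surface-potential battery whose light-induced change is proportional to
the cis fraction:

    dV_s(t) = alpha * asym * n_cis(t)

`alpha` (volts per unit cis fraction per unit asymmetry) lumps the
dipole surface density and the double-layer response; `asym` is the
Boltzmann leaflet asymmetry above.  `V_s` couples to the membrane node
through a hybrid element chosen so that one circuit reproduces all four
qualitative signatures of the recordings: a coupling capacitance `C_s`
(fast displacement pathway → sharp on-peak within 10 ms, post-pulse
hyperpolarizing rebound, ~2 ms voltage-clamp current peak) in parallel
with a coupling conductance `G_s` (sustained pathway → depolarization
plateau during the pulse and the voltage-clamp current plateau):

    C_m dΔV_m/dt = −ΔV_m/R_m + C_s dΔV_s/dt + G_s ΔV_s        (current clamp)
    I = −(C_s dΔV_s/dt + G_s ΔV_s) + (V_hold − V_rest)/R_m    (voltage clamp)

Inward currents are negative, depolarizations positive.

Numerics.  The sampled drive is read as zero-order hold and the
transformed state `w = ΔV_m − (C_s/C_m) ΔV_s` is advanced with the
exact per-interval exponential update (a first-order linear recurrence
evaluated by `scipy.signal.lfilter`).  This is unconditionally stable,
machine-exact for step drives (the capacitive jump is algebraic, not an
impulse), and O(dt) for smooth drives — negligible at 10 kHz sampling
against millisecond kinetics.  Voltage-clamp capacitive currents use
the analytic `dn_cis/dt` carried by the population trace (the
rate-equation right-hand side), avoiding finite differencing.  An
optional causal 4-pole Bessel low-pass (2 kHz) emulates the acquisition
filter.

Coupling defaults.  `alpha = 0.3 V`, `C_s = 9.58 pF`, `G_s = 0.614 nS`
were solved (once, analytically anchored) so that the default kinetics
reproduce both measured HEK population means at the highest dose —
+3.0 mV peak depolarization and −0.7 mV post-pulse hyperpolarization
for 10 µM loading at 105 mW mm⁻², 20 ms pulses.  Only the products
`alpha*asym`, `C_s/C_m` and `G_s R_m` affect the voltage output (see
Identifiability).

Peak metrics follow the experimental convention: baseline = mean over
the 50 ms before light onset; depolarization peak = max deviation
within 300 ms of onset; hyperpolarization = signed minimum within
300 ms of light-off.  Membrane capacitance is estimated from a 5 mV
test step as `C = ΔQ/ΔV` with `ΔQ` the leak-subtracted transient area
(trapezoid), leak taken from the post-transient steady level.

## Transient-absorption analysis

ΔT/T maps use the convention positive = ground-state bleach (GSB) /
stimulated emission, negative = photoinduced or product-state (cis)
absorption.  Band-integrated kinetics (mean over `lambda0 ± half_width`)
are fitted with a mono-exponential model by particle-swarm optimization
followed by a Nelder–Mead polish.  PSO settings (none are dictated by
the physics): 50 particles, 500 iterations, inertia 0.72,
cognitive/social 1.49 (standard constriction), reflecting box walls,
seeded; early stop after 80 stagnant iterations; the polish is
evaluated clipped into the box and never accepted if it worsens the
objective.  Fits minimise unweighted least squares.  Time zero is fixed
to the first sample for microsecond traces (instrument response
unresolved there) and may be floated for picosecond traces.  The sub-ns
two-component behaviour is modelled as mono-exponential + plateau.

Pile-up: under repetitive pumping (2 Hz, `T_rep = 0.5 s`) a slow decay
leaves residual signal between pulses; the recurrence
`r_{n+1} = (r_n + A) e^{−T_rep/tau}` has fixed point
`r_inf = A x/(1 − x)`, `x = e^{−T_rep/tau}`.  The pile-up-aware fit
pins the model baseline to `r_inf(A, tau)` (a free offset would be
exactly collinear with it).

Two-population decomposition: a micelle-suspension decay is
`A [f e^{−t/tau_fixed} + (1−f) e^{−t/tau_free}] + y0` with the aqueous
lifetime held fixed — the sense in which the micellar lifetime is an
average over molecules in micelles and in water (amplitude-weighted
mean lifetime `f tau_fixed + (1−f) tau_free`).  One PSO particle is
seeded at the pure fixed-lifetime corner so the search cannot be
trapped in the long-lifetime/offset degeneracy; `tau_free` beyond ~3×
the trace span, or `f` at the ends, is flagged unidentifiable.

## Synthetic data generator

No raw recordings are distributed, so seeded generators emulate the
experiments and write their ground truth into the ensemble manifest;
closed-loop recovery (generate → analyse → compare) is the testable
contract.

Current clamp: groups are (concentration ∈ {0, 5, 10 µM}) ×
(intensity ∈ {27, 54, 79, 105 mW mm⁻²}) × (pulse ∈ {20, 200 ms}),
10 kHz sampling, 2 kHz Bessel filtering.  Each cell draws
`V_rest ~ N(−35, 8) mV` truncated to [−90, −10]; its response is the
forward model scaled by (i) the Boltzmann asymmetry at its own
`V_rest` (producing the amplitude/V_rest covariation), (ii) a
concentration factor (0.5 at 5 µM), and (iii) an anchor that pins the
reference-cell peak at 10 µM / 105 mW mm⁻² to exactly 3.0 mV — the
measured population mean.  Other intensities follow the forward model
itself (approximately the photostationary law).  Acquisition noise is
additive Gaussian (0.15 mV SD) plus a 0.3 mV, 1 Hz sinusoidal drift
with random phase.  Vehicle groups carry noise and drift only.

Voltage clamp: 11 holding potentials (−100…+100 mV in 20 mV steps) per
cell, leak `(V_hold − V_rest)/R_m`, light-evoked current from the same
circuit, 5 pA noise.

TA fixtures: Gaussian GSB band (520 nm water / 500 nm SDS) and a
negative cis band below 400 nm decaying with the medium lifetime
(42/300 µs) in the microsecond regime; fast component (2.7/2.2 ps) plus
plateau and a negative PIA band in the picosecond regime.

What the generator does **not** emulate: channel noise spectra, series
resistance and electrode artifacts, action potentials, cell-to-cell
kinetic heterogeneity, chirp or solvent response in TA.  Passing
closed-loop tests therefore demonstrates the correctness and the
statistical behaviour of the analysis chain under the stated noise
model, not performance on raw laboratory data.

## Calibration

The coupled model is fitted to per-group mean traces over
[−50 ms, pulse + 300 ms] around light onset, all non-vehicle groups
jointly, unweighted least squares, PSO + polish (40 particles, up to
250 iterations).  Two pre-processing steps, both possible on real
recordings, precede averaging:

* **Resting-potential normalisation.**  Response amplitude covaries
  with `V_rest` through the Boltzmann asymmetry; each cell's
  baseline-subtracted trace is rescaled to the −35 mV reference using
  the asymmetry at its own measured baseline.  Without this, the
  finite-sample spread of resting potentials leaves ~5% random
  amplitude error per group at n = 20.
* **Drift removal.**  A quadratic fitted to the signal-free flanks of
  the window (pre-onset, and > 150 ms after light-off where the
  response has decayed) is subtracted per group.

Identifiability.  The voltage output depends on the drive only through
products, leaving two exact scale degeneracies in the naive parameter
set {`alpha_asym`, `C_s/C_m`, `G_s R_m`, `kappa_TC`, `kappa_CT`,
`gamma`}: (i) `alpha_asym` versus the two coupling gains, and (ii)
`alpha_asym` versus the `kappa_TC`/`kappa_CT` split at fixed total
rate (rescaling the cis amplitude while preserving every relaxation
rate at every intensity).  By default the fit pins `C_s/C_m` (available
from the independent capacitance characterization) and `kappa_CT`
(from the photophysical steady-state analysis), leaving
{`alpha_asym`, `G_s R_m`, `kappa_TC`, `gamma`} free — all identifiable.
Passing `fixed={}` fits everything and accepts the degeneracy
(predictions are unchanged; individual parameter values are not
meaningful).  Closed-loop tests recover the gain within 10% and the
kinetic time constants within 20% at 8–20 cells/group; at 20 cells the
calibrated model reproduces the 3.0 / −0.7 mV anchor amplitudes within
±0.1 mV.  Uncertainty comes from a cell-level bootstrap (resample
cells within groups, simplex refit from the point estimate).

Temperature is fixed per preparation (298.15 K default; 296 K for
room-temperature neuron recordings, 308.15 K for cardiomyocytes at
35 °C) — it enters only through the asymmetry normalisation.

## Problem sizes

Default analysis and test runs use: 9 groups × 20 cells × 5201 samples
for the calibration ensemble; 100 seeded replicates for Monte-Carlo
recovery checks; N = 10⁴ molecules for stochastic flip-flop checks;
1 µs grids where quadrature-level accuracy is asserted.  These sizes
make every statistical tolerance in the test suite comfortably
resolvable while keeping a full run on one CPU in minutes.

## Known limitations

* The exact equivalent-circuit topology used by the original analysis
  is not published; the hybrid C_s/G_s coupling is this package's
  choice, justified by reproducing the four qualitative signatures
  listed above.
* Which dipole (trans, cis, or average) enters the orientation ratio is
  ambiguous at the ~2% level (1.223 vs a printed ≈1.25); the trans
  value is used by default and the dipole is an argument.
* The membrane-phase cis lifetime default (1 ms) is a modelling choice,
  overridden by calibration.
* Neuronal/cardiomyocyte intrinsic conductances that repolarize during
  200 ms pulses are outside the circuit; the model represents their
  effect only through cis-population saturation plus capacitive decay.
* `Cm = ΔQ/ΔT` as sometimes written for the capacitance test is
  dimensionally inconsistent; the estimator implements `ΔQ/ΔV_step`.
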