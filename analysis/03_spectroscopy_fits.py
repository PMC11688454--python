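#!/usr/bin/env python
"""Transient-absorption decay analysis on synthetic maps.

Generates microsecond-regime dT/T maps for water and SDS micelle
suspensions (known injected lifetimes: 42 us and 300 us), extracts the
band-integrated ground-state-bleach kinetics, and fits them with the
particle-swarm mono-exponential procedure.  Also demonstrates the
pile-up correction for slow decays under 2 Hz repetitive pumping and the
two-population decomposition of a micelle-suspension decay.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from photodipole._pso import PSOConfig
from photodipole.spectrofit import (gsb_band_dynamics, fit_monoexp_pso,
                                    fit_two_population, pileup_steady_offset)
from photodipole.synthetic_data import gen_ta_fixture


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    report = {}

    for medium in ("water", "SDS"):
        m = gen_ta_fixture(medium, "us", noise_sd=5e-5, seed=args.seed)
        trace = gsb_band_dynamics(m, m.meta["gsb_center_nm"], 10.0)
        fit = fit_monoexp_pso(m.delays, trace, pso_config=PSOConfig(seed=args.seed))
        err = abs(fit.tau - m.meta["tau_s"]) / m.meta["tau_s"]
        report[medium] = {"tau_injected_us": m.meta["tau_s"] * 1e6,
                          "tau_fitted_us": fit.tau * 1e6,
                          "relative_error": err, "sse": fit.sse}
        print(f"{medium}: GSB band at {m.meta['gsb_center_nm']:.0f} nm, "
              f"fitted cis lifetime {fit.tau * 1e6:.1f} us "
              f"(injected {m.meta['tau_s'] * 1e6:.0f} us, error {err * 100:.2f}%)")

    # pile-up: a 400 ms decay pumped at 2 Hz leaves a steady residual
    tau, T_rep = 0.4, 0.5
    r_inf = pileup_steady_offset(1.0, tau, T_rep)
    t = np.linspace(0, 2.0, 200)
    y = np.exp(-t / tau) + r_inf
    fit = fit_monoexp_pso(t, y, pso_config=PSOConfig(seed=args.seed),
                          pileup=True, T_rep=T_rep)
    print(f"\nPile-up at 2 Hz pumping, tau = {tau:.1f} s: steady residual "
          f"{r_inf:.3f} x amplitude; pile-up-aware fit recovers tau = "
          f"{fit.tau:.4f} s")
    report["pileup"] = {"tau_s": fit.tau, "steady_residual": r_inf}

    # micelle suspension as a two-population average
    t2 = np.linspace(0, 1.5e-3, 300)
    y2 = 0.4 * np.exp(-t2 / 42e-6) + 0.6 * np.exp(-t2 / 300e-6)
    two = fit_two_population(t2, y2, 42e-6, seed=args.seed)
    print(f"\nTwo-population decomposition (aqueous lifetime fixed at 42 us): "
          f"f_water = {two.f:.3f}, tau_micelle = {two.tau_free * 1e6:.1f} us, "
          f"amplitude-weighted mean lifetime {two.mean_lifetime * 1e6:.0f} us")
    report["two_population"] = {"f": two.f, "tau_free_us": two.tau_free * 1e6,
                                "mean_lifetime_us": two.mean_lifetime * 1e6}

    with open(args.out / "ta_fits.json", "w") as fh:
        json.dump(report, fh, indent=1)
    print(f"\nwrote {args.out / 'ta_fits.json'}")


if __name__ == "__main__":
    main()
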