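#!/usr/bin/env python
"""Photoswitch population kinetics under the experimental light doses.

Computes the photostationary cis fraction across the four power
densities used in the patch-clamp experiments (27/54/79/105 mW mm^-2),
and the full population time course for 20 ms and 200 ms pulses at the
highest dose.  Writes a summary table and example traces under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from photodipole.photokinetics import (LightProtocol, PhotoswitchParams,
                                       photostationary_fractions,
                                       simulate_populations)
from photodipole.io import write_population_trace

INTENSITIES = [27.0, 54.0, 79.0, 105.0]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--traces-dir", type=Path, default=Path("scratch"),
                    help="where the (bulky) sampled traces go")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    args.traces_dir.mkdir(parents=True, exist_ok=True)

    params = PhotoswitchParams()
    rows = []
    for I in INTENSITIES:
        n_trans, n_cis = photostationary_fractions(I, params)
        k_tot = (params.kappa_TC + params.kappa_CT) * I + params.gamma
        rows.append({"intensity_mWmm2": I, "n_cis_ss": n_cis,
                     "n_trans_ss": n_trans, "tau_on_ms": 1e3 / k_tot})
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "photostationary_fractions.csv", index=False)
    print("Photostationary state under the experimental doses "
          "(tau_cis = 1 ms membrane default):")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

    for pulse_ms in (20.0, 200.0):
        proto = LightProtocol.pulse(0.05, pulse_ms * 1e-3, 0.3, 105.0)
        pop = simulate_populations(proto, params, dt_out=1e-4)
        path = args.traces_dir / f"population_105mWmm2_{int(pulse_ms)}ms.csv"
        write_population_trace(pop, path)
        print(f"\n{pulse_ms:.0f} ms pulse at 105 mW mm^-2: cis fraction "
              f"peaks at {pop.n_cis.max():.3f}, reaches steady state within "
              f"{5e3 / ((params.kappa_TC + params.kappa_CT) * 105 + params.gamma):.2f} ms; "
              f"trace -> {path}")

    print("\nThe cis population saturates within a few on-time constants and "
          "holds constant for the rest of the pulse -- the surface-potential "
          "drive is a filtered replica of this time course.")


if __name__ == "__main__":
    main()
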