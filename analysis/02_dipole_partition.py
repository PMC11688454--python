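#!/usr/bin/env python
"""Boltzmann partitioning of the molecular dipole in the membrane field.

Evaluates the orientation ratio and leaflet excess for the trans dipole
(12.4 D) in the ~1e7 V/m transmembrane field, the dipole change on
isomerisation in SI units, the predicted photoresponse-vs-resting-
potential curve, and reduced flip-flop simulations at increasing
transmembrane voltages.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from photodipole import dipole_partition as dp


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    field = dp.MembraneField(E=1e7, T=298.15)
    r = dp.orientation_ratio(12.4, field)
    excess, asym = dp.excess_and_asymmetry(r)
    dmu = dp.debye_to_coulomb_meter(12.4 - 8.6)
    print(f"Orientation ratio exp(2 mu E / kB T) at 12.4 D, 1e7 V/m, 298 K: "
          f"{r:.4f}")
    print(f"  -> {excess * 100:.1f}% excess of field-aligned molecules "
          f"(normalised asymmetry {asym:.4f})")
    print(f"Dipole change on trans->cis isomerisation: 3.8 D = {dmu:.4g} C m")

    V = np.linspace(-0.100, 0.0, 51)
    amp = dp.photoresponse_vs_resting_potential(V)
    pd.DataFrame({"V_rest_V": V, "relative_amplitude": amp}).to_csv(
        args.out / "photoresponse_vs_vrest.csv", index=False)
    coef = np.polynomial.polynomial.polyfit(V, amp, 1)
    resid = amp - np.polynomial.polynomial.polyval(V, coef)
    print(f"\nPredicted photoresponse amplitude is within "
          f"{100 * np.max(np.abs(resid)) / (amp.max() - amp.min()):.2f}% of a "
          f"straight line over [-100, 0] mV -- consistent with the measured "
          f"linear amplitude/V_rest correlation.")

    rows = []
    n_rep = 25
    seeds = np.random.SeedSequence(args.seed).spawn(n_rep)
    for V_m in (-0.050, -0.200, -0.500):
        f = dp.MembraneField(E=dp.field_from_potential(abs(V_m), 5e-9))
        net = []
        for s in seeds:
            state = dp.LeafletState(N_out=15.0, N_in=15.0)
            _, _, n_in = dp.simulate_flipflop(state, 12.4, f, base_rate=1.0,
                                              duration=2.0, mode="stochastic",
                                              seed=s)
            net.append(n_in[-1] - 15.0)
        rows.append({"V_m_mV": V_m * 1e3,
                     "ratio_eq": dp.orientation_ratio(12.4, f),
                     "mean_net_out_to_in_flips": float(np.mean(net)),
                     "sem": float(np.std(net, ddof=1) / np.sqrt(n_rep))})
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "flipflop_vs_voltage.csv", index=False)
    print(f"\nFlip-flop bias grows with the transmembrane voltage "
          f"(30 molecules, 2 s window, mean of {n_rep} runs):")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
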