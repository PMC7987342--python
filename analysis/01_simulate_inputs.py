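#!/usr/bin/env python
"""Generate the synthetic study inputs for the downstream analyses.

Emulates the three data streams of a time-resolved channelrhodopsin study
with known ground truth: (a) a dark/light toy crystal pair (one sulfur atom
shifted 0.6 A) with observed amplitudes of a 30%-activation mixture, (b) a
transient-absorption matrix of the sequential P1(520) -> P2(390) -> P3(520)
photocycle, (c) a voltage family of laser-flash photocurrents.  Everything is
written in the text formats the later analysis steps (and the package's own
readers) consume.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from kinemap.crystal_core import write_amplitudes, write_model
from kinemap.kinetics_spectra import write_spectra_csv
from kinemap.synthetic_data import (
    DEFAULT_PHOTOCYCLE,
    make_toy_crystal_pair,
    simulate_photocurrent,
    simulate_photocycle_spectra,
    simulate_tr_reflections,
)

R_TRUE = 0.30          # activation fraction (quantum efficiency of isomerisation)
NOISE_FRAC = 0.05      # amplitude noise, fraction of mean |F|
D_MIN = 1.8            # resolution cutoff of the toy data (A)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/inputs"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    dark, light = make_toy_crystal_pair(args.seed)
    (out / "dark.pdb").write_text(write_model(dark))
    (out / "light.pdb").write_text(write_model(light))
    d_obs, l_obs = simulate_tr_reflections(dark, light, R_TRUE, NOISE_FRAC,
                                           args.seed + 100, D_MIN)
    (out / "dark.hkl").write_text(write_amplitudes(d_obs))
    (out / "light.hkl").write_text(write_amplitudes(l_obs))
    print(f"crystal pair: {dark.n_atoms} atoms, S15 shifted 0.6 A; "
          f"{len(d_obs)} reflections to {D_MIN} A at R_true={R_TRUE}, "
          f"{NOISE_FRAC:.0%} amplitude noise")

    times = np.geomspace(1e-6, 50e-3, 60)
    wl = np.arange(340.0, 621.0, 4.0)
    A = simulate_photocycle_spectra(DEFAULT_PHOTOCYCLE, times, wl,
                                    noise_sd=2e-3, seed=args.seed + 200)
    write_spectra_csv(A, str(out / "dA.csv"))
    print(f"photocycle spectra: {A.dA.shape[0]} wavelengths x {A.dA.shape[1]} delays, "
          f"tau(P1->P2)={1e3 / DEFAULT_PHOTOCYCLE.k2:.2f} ms, "
          f"tau(P2->P3)={1e3 / DEFAULT_PHOTOCYCLE.k3:.2f} ms")

    volts = np.array([-60.0, -30.0, 0.0, 30.0, 60.0])
    traces = simulate_photocurrent(volts, noise_sd=1.0, seed=args.seed + 300)
    for tr in traces:
        pd.DataFrame({"time_s": tr.t, "current_pA": tr.I,
                      "voltage_mV": tr.voltage, "pH": tr.pH}
                     ).to_csv(out / f"trace_{int(tr.voltage):+d}mV.csv", index=False)
    print(f"photocurrents: {len(traces)} voltages, passive decay "
          f"tau_fast=20 ms / tau_slow=100 ms, reversal 0 mV")


if __name__ == "__main__":
    main()
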