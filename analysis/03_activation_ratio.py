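#!/usr/bin/env python
"""Estimate the activation ratio R by the extrapolation-map disappearance scan
and write the extrapolated structure-factor amplitudes at the estimated R.

F_extra = (F_o^light - F_o^dark)/R + F_o^dark is scanned for R from 1.0
downward in steps of 0.01; at each step the extrapolated map (dark phases) is
synthesized and the density at a probe on the vacated lobe of the shifted
sulfur is monitored.  The largest R at which that dark-state feature has
disappeared (drops below the criterion threshold) is the estimate.  The
generator's truth here is R_true = 0.30.
"""

import argparse
import json
from pathlib import Path

from kinemap.crystal_core import read_amplitudes, read_model, write_amplitudes
from kinemap.extrapolation import estimate_activation_ratio, extrapolated_map
from kinemap.maps import write_ccp4
from kinemap.scaling import apply_scale, fit_scale
from kinemap.structure_factors import calc_fc

D_MIN = 1.8


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", type=Path, default=Path("results/inputs"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    dark_model = read_model((args.inputs / "dark.pdb").read_text(), label="dark")
    d_obs = read_amplitudes((args.inputs / "dark.hkl").read_text(), label="dark")
    l_obs = read_amplitudes((args.inputs / "light.hkl").read_text(), label="light")
    l_s = apply_scale(l_obs, fit_scale(l_obs, d_obs, dark_model.cell), dark_model.cell)
    phases = calc_fc(dark_model, d_obs.hkl)

    res = estimate_activation_ratio(l_s, d_obs, phases, dark_model,
                                    d_min=D_MIN, cell=dark_model.cell)
    probe = tuple(round(float(x), 3) for x in res.probe_site)
    print(f"activation ratio R = {res.R:.2f} "
          f"(criterion: |height| < {res.criterion_threshold} sigma at probe "
          f"{probe}; {res.n_negative} negative extrapolated amplitudes retained)")
    print("note: single replicates scatter by ~0.08 around the generating ratio "
          "(the shifted atom's random B-factor and local background); "
          "scripts/acceptance.py reports the 10-replicate ensemble mean")

    (args.out / "extrapolated.hkl").write_text(write_amplitudes(res.F_extra))
    write_ccp4(extrapolated_map(l_s, d_obs, phases, res.R, D_MIN, dark_model.cell),
               str(args.out / "extrapolated_map.ccp4"))
    with (args.out / "activation_scan_trace.tsv").open("w") as fh:
        fh.write("R\theight_sigma\n")
        for r, h in res.scan_trace:
            fh.write(f"{r:.3f}\t{h:+.5f}\n")
    (args.out / "activation_ratio.json").write_text(json.dumps({
        "R": res.R,
        "criterion_threshold_sigma": res.criterion_threshold,
        "probe_site_frac": list(res.probe_site),
        "n_negative_F_extra": res.n_negative,
    }, indent=2))


if __name__ == "__main__":
    main()
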