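#!/usr/bin/env python
"""Recompute the experiment-design worked values.

Four pure unit conversions that pin down the pump-probe geometry and sample
preparation: the LCP jet's linear speed, the spacing between consecutively
pumped jet segments, the flash-photolysis pump fluence, and the liposome
reconstitution lipid concentration.  Quoted at 2 significant figures, the
convention for such numbers.
"""

import argparse
import json
from pathlib import Path

from kinemap.experiment_geometry import (
    fluence,
    jet_linear_speed,
    pump_separation,
    reconstitution_lipid_conc,
    round_sig,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    speed = jet_linear_speed(2.5, 75.0)
    sep = pump_separation(round_sig(speed), 15.0)
    flu = fluence(15.0, 300.0)
    lipid = reconstitution_lipid_conc(5.0, 50.0)

    rows = [
        ("jet speed (2.5 ul/min, 75 um nozzle)", speed, round_sig(speed), "mm/s"),
        ("pump separation (9.4 mm/s, 15 Hz)", sep, round_sig(sep), "um"),
        ("pump fluence (15 uJ, 300 um beam)", flu, round_sig(flu), "nJ/um^2"),
        ("lipid conc (5 uM protein, 1:50)", lipid, round_sig(lipid), "uM"),
    ]
    for name, full, rounded, unit in rows:
        print(f"{name}: {full:.4g} -> {rounded:g} {unit}")

    (args.out / "geometry.json").write_text(json.dumps(
        {name: {"value": full, "rounded_2sf": rounded, "unit": unit}
         for name, full, rounded, unit in rows}, indent=2))


if __name__ == "__main__":
    main()
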