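"""Pump-probe experiment-design arithmetic.

Pure unit conversions a beamline scientist does on the back of an envelope:
linear jet speed from a volumetric flow rate, pump-spot separation along the
jet from the pump repetition rate, pump fluence from pulse energy and beam
diameter, and the lipid concentration for proteoliposome reconstitution.
Full precision is returned; :func:`round_sig` provides the 2-significant-
figure display convention used when quoting these numbers.

Note the fluence unit: energy per *area* (nJ/um^2); a per-length "nJ/um" is
dimensionally inconsistent and is not used here.
"""

from __future__ import annotations

import math

__all__ = [
    "jet_linear_speed",
    "pump_separation",
    "fluence",
    "reconstitution_lipid_conc",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def jet_linear_speed(volumetric_rate_ul_min: float, nozzle_inner_diameter_um: float) -> float:
    """Linear speed (mm/s) of a jet extruded through a circular nozzle.

    Volumetric rate in ul/min, nozzle inner diameter in um.
    """
    if volumetric_rate_ul_min <= 0 or nozzle_inner_diameter_um <= 0:
        raise ValueError("flow rate and nozzle diameter must be > 0")
    rate_um3_s = volumetric_rate_ul_min * 1e9 / 60.0
    area_um2 = math.pi * (nozzle_inner_diameter_um / 2.0) ** 2
    return rate_um3_s / area_um2 / 1e3          # um/s -> mm/s


def pump_separation(linear_speed_mm_s: float, pump_rate_hz: float) -> float:
    """Distance (um) the jet travels between successive pump pulses."""
    if pump_rate_hz <= 0:
        raise ValueError("pump rate must be > 0")
    if linear_speed_mm_s < 0:
        raise ValueError("speed must be >= 0")
    return linear_speed_mm_s / pump_rate_hz * 1e3


def fluence(pulse_energy_uj: float, beam_diameter_um: float) -> float:
    """Pump fluence (nJ/um^2) of a pulse spread over a circular beam spot."""
    if pulse_energy_uj <= 0 or beam_diameter_um <= 0:
        raise ValueError("pulse energy and beam diameter must be > 0")
    area_um2 = math.pi * (beam_diameter_um / 2.0) ** 2
    return pulse_energy_uj * 1e3 / area_um2


def reconstitution_lipid_conc(protein_conc_um: float, lipid_per_protein: float) -> float:
    """Lipid concentration (uM) for a given protein concentration (uM) and
    lipid:protein molar ratio."""
    if protein_conc_um <= 0 or lipid_per_protein <= 0:
        raise ValueError("concentration and molar ratio must be > 0")
    return protein_conc_um * lipid_per_protein
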