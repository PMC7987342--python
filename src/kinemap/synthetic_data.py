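"""Synthetic ground-truth generators for every stage of the pipeline.

Real time-resolved serial-crystallography, flash-photolysis and patch-clamp
data are large and instrument-specific; each generator here emulates the
*mathematical structure* of one input with full knowledge of the truth, so
that every downstream operation can be tested as a parameter-recovery
problem:

* toy dark/light crystal pairs differing by sub-Angstrom rigid shifts of
  selected atoms,
* observed amplitudes of a partial-occupancy mixture at a known activation
  ratio R (complex-valued mixing of structure factors, Gaussian amplitude
  noise),
* transient-absorption matrices following the sequential rhodopsin-style
  photocycle P1(520 nm) -> P2(390 nm) -> P3(520 nm), solved analytically,
* voltage-dependent photocurrents: a voltage-independent fast charge-transfer
  transient plus a passive component proportional to (V - V_rev) with a
  single-exponential rise and biexponential decay.

Mixing for the light observation is complex-valued (a partial-occupancy
superposition of scatterers), while the extrapolation stage operates on
amplitudes: that deliberate mismatch is exactly the linear-approximation
regime the amplitude-extrapolation formula assumes.

All generators are deterministic under a fixed seed and attach truth
metadata sufficient for the recovery tests.  The default activation fraction
used in demonstrations is 0.30, matching the low quantum efficiency of
retinal isomerisation in the C1C2 chimera.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal_core import AmplitudeSet, AtomicModel, UnitCell, generate_hkl
from .kinetics_spectra import SpectraMatrix
from .photocurrent import CurrentTrace
from .structure_factors import calc_fc

__all__ = [
    "ShiftSpec",
    "Species",
    "PhotocycleModel",
    "DEFAULT_CELL",
    "DEFAULT_PHOTOCYCLE",
    "make_toy_crystal_pair",
    "simulate_tr_reflections",
    "simulate_photocycle_spectra",
    "simulate_photocurrent",
]

DEFAULT_CELL = UnitCell(20.0, 18.0, 16.0, 90.0, 96.0, 90.0)


@dataclass(frozen=True)
class ShiftSpec:
    """Rigid displacement of selected atoms (orthogonal Angstrom vector)."""

    atom_indices: tuple[int, ...]
    displacement: tuple[float, float, float]
    description: str = ""

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.displacement))


def make_toy_crystal_pair(
    seed: int,
    n_atoms: int = 15,
    cell: UnitCell = DEFAULT_CELL,
    shift: ShiftSpec | None = None,
) -> tuple[AtomicModel, AtomicModel]:
    """Random non-clashing toy model pair: a dark model and a light model in
    which the atoms selected by ``shift`` are rigidly displaced.

    The dark model mixes C/N/O with one sulfur (atom index n_atoms-1 by
    default the shifted one, emulating a cysteine SG); B-factors are uniform
    in [10, 40] A^2, occupancies 1.  Default shift: the sulfur moved 0.6 A.
    """
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    rng = np.random.default_rng(seed)
    if shift is None:
        shift = ShiftSpec(atom_indices=(n_atoms - 1,), displacement=(0.6, 0.0, 0.0),
                          description="0.6 A shift of the sulfur atom")
    if shift.magnitude <= 0:
        raise ValueError("shift displacement must be non-zero")
    if shift.magnitude > min(cell.a, cell.b, cell.c) / 2:
        raise ValueError("shift larger than half the cell")
    if any(i >= n_atoms or i < 0 for i in shift.atom_indices):
        raise ValueError("shift selects non-existent atoms")

    # rejection-sample fractional positions with a 2.0 A minimum separation
    frac: list[np.ndarray] = []
    cart: list[np.ndarray] = []
    while len(frac) < n_atoms:
        x = rng.uniform(0, 1, size=3)
        xc = cell.orthogonalize(x)
        ok = True
        for yc in cart:
            d = cell.fractionalize(xc - yc)
            d -= np.rint(d)
            if np.linalg.norm(cell.orthogonalize(d)) < 2.0:
                ok = False
                break
        if ok:
            frac.append(x)
            cart.append(xc)
    frac_arr = np.asarray(frac)
    elements = list(rng.choice(["C", "C", "N", "O"], size=n_atoms))
    elements[n_atoms - 1] = "S"
    b = rng.uniform(10.0, 40.0, size=n_atoms)
    dark = AtomicModel(
        cell=cell,
        elements=tuple(elements),
        frac=frac_arr,
        occ=np.ones(n_atoms),
        b_iso=b,
        label="dark",
    )
    light = dark.copy(label="light")
    dfrac = cell.fractionalize(np.asarray(shift.displacement, dtype=float))
    light.frac = light.frac.copy()
    light.frac[list(shift.atom_indices)] += dfrac
    light.meta = {"shift": shift}  # type: ignore[attr-defined]
    return dark, light


def simulate_tr_reflections(
    dark: AtomicModel,
    light: AtomicModel,
    R_true: float,
    noise_frac: float,
    seed: int,
    d_min: float = 1.8,
) -> tuple[AmplitudeSet, AmplitudeSet]:
    """Observed dark/light amplitude pair of a partial-activation mixture.

    F_light_mix = (1 - R_true) Fc_dark + R_true Fc_light (complex mixing);
    observed amplitudes are |.| plus Gaussian noise of standard deviation
    ``noise_frac * mean|F|`` (folded positive), with sigF set to that sigma.
    Truth metadata (R_true, noise level, cell, d_min) rides on ``meta``.
    """
    if not 0.0 <= R_true <= 1.0:
        raise ValueError("R_true must lie in [0, 1]")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    rng = np.random.default_rng(seed)
    hkl = generate_hkl(dark.cell, d_min)
    fc_d = calc_fc(dark, hkl)
    fc_l = calc_fc(light, hkl)
    mix = (1.0 - R_true) * fc_d.F_complex + R_true * fc_l.F_complex
    amp_d = np.abs(fc_d.F_complex)
    amp_l = np.abs(mix)
    sigma = noise_frac * float(np.mean(amp_d))
    if sigma > 0:
        # merged data carry one amplitude per Friedel pair: draw the noise on
        # a unique half-set and mirror it onto the mates
        keys = {}
        for i, row in enumerate(map(tuple, hkl.tolist())):
            canon = max(row, tuple(-x for x in row))
            keys.setdefault(canon, []).append(i)
        eps_d = np.empty(len(hkl))
        eps_l = np.empty(len(hkl))
        for idxs in keys.values():
            eps_d[idxs] = rng.normal(0.0, sigma)
            eps_l[idxs] = rng.normal(0.0, sigma)
    else:
        eps_d = eps_l = 0.0
    truth = {
        "R_true": R_true,
        "noise_frac": noise_frac,
        "noise_sigma": sigma,
        "seed": seed,
        "d_min": d_min,
        "cell": dark.cell,
    }
    dark_obs = AmplitudeSet(
        hkl=hkl, F=np.abs(amp_d + eps_d), sigF=np.full(len(hkl), sigma),
        label="dark_obs", d_min=d_min, meta=dict(truth),
    )
    light_obs = AmplitudeSet(
        hkl=hkl, F=np.abs(amp_l + eps_l), sigF=np.full(len(hkl), sigma),
        label=f"light_obs_R{R_true:g}", d_min=d_min, meta=dict(truth),
    )
    return dark_obs, light_obs


# --------------------------------------------------------------------------
# Photocycle spectra
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    """One spectral species: Gaussian absorption band on a wavelength axis."""

    name: str
    lambda_max: float         # nm
    bandwidth: float          # nm (Gaussian sigma)
    extinction: float         # peak extinction (arbitrary absorbance units)

    def spectrum(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return self.extinction * np.exp(-((wl - self.lambda_max) ** 2) / (2 * self.bandwidth**2))


@dataclass(frozen=True)
class PhotocycleModel:
    """Sequential three-intermediate photocycle.

    Excitation instantaneously converts a fraction ``phi`` of the ground
    state into P1; P1 -> P2 with rate k2 and P2 -> P3 with rate k3 (P3 does
    not decay on the modelled window).  Concentrations therefore satisfy
    c_P1 + c_P2 + c_P3 = phi at every time.
    """

    ground: Species
    p1: Species
    p2: Species
    p3: Species
    k2: float                 # 1/s, P1 -> P2
    k3: float                 # 1/s, P2 -> P3
    phi: float = 0.3          # excited fraction

    def __post_init__(self) -> None:
        if self.k2 <= 0 or self.k3 <= 0:
            raise ValueError("rates must be > 0")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")

    def concentrations(self, times: np.ndarray) -> np.ndarray:
        """Analytic concentrations (3, n_times) of P1, P2, P3."""
        t = np.asarray(times, dtype=float)
        k2, k3, phi = self.k2, self.k3, self.phi
        c1 = phi * np.exp(-k2 * t)
        if abs(k2 - k3) > 1e-12 * max(k2, k3):
            c2 = phi * k2 / (k3 - k2) * (np.exp(-k2 * t) - np.exp(-k3 * t))
        else:
            c2 = phi * k2 * t * np.exp(-k2 * t)
        c3 = phi - c1 - c2
        return np.stack([c1, c2, c3])

    @property
    def t_max_p2(self) -> float:
        """Analytic time of maximal P2 concentration, ln(k2/k3)/(k2-k3)."""
        if abs(self.k2 - self.k3) < 1e-12 * max(self.k2, self.k3):
            return 1.0 / self.k2
        return float(np.log(self.k2 / self.k3) / (self.k2 - self.k3))


DEFAULT_PHOTOCYCLE = PhotocycleModel(
    ground=Species("ground", 470.0, 30.0, 1.0),
    p1=Species("P1", 520.0, 30.0, 1.0),
    p2=Species("P2", 390.0, 25.0, 0.9),
    p3=Species("P3", 520.0, 30.0, 1.0),
    k2=1.0 / 500e-6,          # P1 -> P2 on the hundreds-of-microseconds scale
    k3=1.0 / 5e-3,            # P2 -> P3 on the milliseconds scale
    phi=0.3,
)


def simulate_photocycle_spectra(
    model: PhotocycleModel,
    times: np.ndarray,
    wavelengths: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SpectraMatrix:
    """Transient-absorption matrix of the sequential photocycle.

    dA(lambda, t) = sum_i c_i(t) (eps_i(lambda) - eps_ground(lambda)) plus
    i.i.d. Gaussian noise of standard deviation ``noise_sd``.
    """
    times = np.asarray(times, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    conc = model.concentrations(times)                       # (3, n_t)
    eg = model.ground.spectrum(wavelengths)
    deps = np.stack([sp.spectrum(wavelengths) - eg for sp in (model.p1, model.p2, model.p3)])
    dA = deps.T @ conc                                       # (n_wl, n_t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dA = dA + rng.normal(0.0, noise_sd, size=dA.shape)
    return SpectraMatrix(wavelengths=wavelengths, times=times, dA=dA)


# --------------------------------------------------------------------------
# Photocurrents
# --------------------------------------------------------------------------

def simulate_photocurrent(
    voltages: np.ndarray,
    reversal_mV: float = 0.0,
    tau_rise: float = 100e-6,
    tau_fast: float = 20e-3,
    tau_slow: float = 100e-3,
    amp_ratio: float = 1.0,
    charge_transfer_amp: float = -50.0,
    conductance_pA_per_mV: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    t: np.ndarray | None = None,
    pH: float = 7.2,
    cell_id: str = "cell1",
) -> list[CurrentTrace]:
    """Family of laser-flash photocurrent traces at the given holding voltages.

    Each trace is the sum of a fast voltage-independent charge-transfer
    transient and a passive component proportional to the driving force
    (V - V_rev), rising with ``tau_rise`` and decaying biexponentially with
    ``tau_fast``/``tau_slow`` (amplitude ratio ``amp_ratio``), plus Gaussian
    noise.  At V = V_rev only the charge-transfer transient remains — the
    same logic by which the 0 mV recording isolates charge transfer.  Truth
    parameters ride on each trace via the generated values themselves
    (deterministic under ``seed``).
    """
    for name, v in (("tau_rise", tau_rise), ("tau_fast", tau_fast), ("tau_slow", tau_slow)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if t is None:
        t = np.concatenate([
            np.linspace(-5e-3, 0, 200, endpoint=False),
            np.geomspace(2e-6, 0.5, 4000),
        ])
    t = np.asarray(t, dtype=float)
    rng = np.random.default_rng(seed)
    wf = amp_ratio / (1.0 + amp_ratio)
    ws = 1.0 / (1.0 + amp_ratio)
    traces = []
    for rep_v in np.atleast_1d(np.asarray(voltages, dtype=float)):
        post = t > 0
        I = np.zeros_like(t)
        tp = t[post]
        # fast charge-transfer transient (voltage independent)
        I[post] += charge_transfer_amp * (np.exp(-tp / 200e-6) - np.exp(-tp / 20e-6))
        # passive component: driving-force scaling, rise then biexponential decay
        drive = (rep_v - reversal_mV) * conductance_pA_per_mV
        I[post] += drive * (1 - np.exp(-tp / tau_rise)) * (
            wf * np.exp(-tp / tau_fast) + ws * np.exp(-tp / tau_slow)
        )
        if noise_sd > 0:
            I = I + rng.normal(0.0, noise_sd, size=len(t))
        traces.append(CurrentTrace(t=t.copy(), I=I, voltage=float(rep_v), pH=pH,
                                   cell_id=cell_id))
    return traces
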