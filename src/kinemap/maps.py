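"""Fourier synthesis of electron-density maps, sigma scaling, peak search and
CCP4/MRC map I/O.

Map synthesis evaluates

    rho(x) = (1/V) * sum_h F(h) exp(-2 pi i h . x)

on a real-space grid.  The production path uses the FFT (placing coefficients
on the reciprocal grid and transforming); :func:`direct_sum_map` evaluates the
identical sum naively and serves as the module's independent oracle.  F(000)
defaults to 0 — difference and extrapolated maps only carry contrast — and may
be supplied explicitly for absolute-density synthesis.

Grid choice: the smallest even dimensions giving a spacing <= d_min/3 (and
large enough to hold every coefficient without aliasing), the standard
oversampling for reliable peak location.  Sigma statistics are computed over
the full cell (P1).  Peak search is a 26-neighbour local-extremum test on the
periodic grid without interpolation; ties break by lexicographic grid index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .crystal_core import AmplitudeSet, AtomicModel, ComplexSFSet, UnitCell

__all__ = [
    "DensityMap",
    "MapPeak",
    "grid_dimensions",
    "synthesize_map",
    "direct_sum_map",
    "difference_map",
    "sigma_scale",
    "find_peaks",
    "write_ccp4",
    "read_ccp4",
]


@dataclass
class DensityMap:
    """Real-space density sampled on an (n_a, n_b, n_c) grid over the cell.

    ``scale_state`` is ``"absolute"`` (e/A^3, as synthesized) or ``"sigma"``
    (mean-subtracted, rms-normalised).
    """

    values: np.ndarray
    cell: UnitCell
    scale_state: str = "absolute"
    d_min: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3-D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def rms(self) -> float:
        return float(self.values.std())

    def value_at(self, frac: np.ndarray) -> float:
        """Density at the grid point nearest a fractional position."""
        frac = np.asarray(frac, dtype=float)
        n = np.asarray(self.shape)
        idx = np.mod(np.rint(frac * n).astype(int), n)
        return float(self.values[tuple(idx)])


@dataclass(frozen=True)
class MapPeak:
    """A signed local extremum of a sigma-scaled map, annotated with the
    nearest model atom under the minimum-image convention."""

    frac: tuple[float, float, float]
    height: float                 # sigma units, signed
    nearest_atom: str
    distance: float               # Angstrom


def grid_dimensions(cell: UnitCell, d_min: float, hkl: np.ndarray | None = None) -> tuple[int, int, int]:
    """Smallest even grid with spacing <= d_min/3 that holds all coefficients."""
    dims = []
    maxidx = (
        np.max(np.abs(np.atleast_2d(hkl)), axis=0) if hkl is not None and len(hkl) else (0, 0, 0)
    )
    for length, m in zip((cell.a, cell.b, cell.c), maxidx):
        n = max(int(math.ceil(3.0 * length / d_min)), 2 * int(m) + 2, 2)
        if n % 2:
            n += 1
        dims.append(n)
    return tuple(dims)  # type: ignore[return-value]


def _coefficient_grid(
    hkl: np.ndarray, F: np.ndarray, dims: tuple[int, int, int], f000: float
) -> np.ndarray:
    """Place coefficients on the reciprocal grid, completing Friedel mates by
    conjugation where absent."""
    grid = np.zeros(dims, dtype=complex)
    n = np.asarray(dims)
    flat = np.ravel_multi_index(tuple(np.mod(hkl, n).T), dims)
    if len(np.unique(flat)) != len(flat):
        raise ValueError("aliasing collision: grid too small for index set")
    gview = grid.reshape(-1)
    gview[flat] = F
    # Friedel completion where the mate is absent
    mate_flat = np.ravel_multi_index(tuple(np.mod(-hkl, n).T), dims)
    absent = ~np.isin(mate_flat, flat)
    gview[mate_flat[absent]] = np.conj(F[absent])
    grid[0, 0, 0] = f000
    return grid


def _as_coeffs(coeffs: ComplexSFSet | tuple[AmplitudeSet, ComplexSFSet]) -> tuple[np.ndarray, np.ndarray]:
    """Accept either a complex SF set or an (amplitudes, phase-source) pair."""
    if isinstance(coeffs, ComplexSFSet):
        return coeffs.hkl, coeffs.F_complex
    ampl, phases = coeffs
    ia, ip = ampl.common_with(phases)
    if len(ia) != len(ampl):
        raise ValueError("phase set does not cover all amplitude indices")
    ph = phases.F_complex[ip]
    unit = np.where(np.abs(ph) > 0, ph / np.where(np.abs(ph) > 0, np.abs(ph), 1.0), 1.0)
    return ampl.hkl[ia], ampl.F[ia] * unit


def synthesize_map(
    coeffs: ComplexSFSet | tuple[AmplitudeSet, ComplexSFSet],
    cell: UnitCell,
    d_min: float,
    f000: float = 0.0,
) -> DensityMap:
    """FFT synthesis of rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x).

    Missing Friedel mates are generated by conjugation.  The imaginary residue
    after transform must not exceed 1e-8 of the map rms (it is discarded).
    """
    hkl, F = _as_coeffs(coeffs)
    if len(hkl) == 0:
        raise ValueError("empty coefficient set")
    dims = grid_dimensions(cell, d_min, hkl)
    grid = _coefficient_grid(hkl, F, dims, f000)
    rho_c = np.fft.fftn(grid) / cell.volume
    rho = rho_c.real
    rms = float(np.sqrt(np.mean(rho * rho)))
    imag = float(np.max(np.abs(rho_c.imag)))
    if rms > 0 and imag > 1e-8 * max(rms, 1e-300):
        raise ValueError(f"non-negligible imaginary component in synthesis ({imag:.3g})")
    return DensityMap(values=rho, cell=cell, scale_state="absolute", d_min=d_min)


def direct_sum_map(
    coeffs: ComplexSFSet | tuple[AmplitudeSet, ComplexSFSet],
    cell: UnitCell,
    grid: tuple[int, int, int],
    f000: float = 0.0,
) -> DensityMap:
    """Naive evaluation of the synthesis sum on the given grid (oracle path).

    Friedel mates are completed by conjugation exactly as in
    :func:`synthesize_map`; the two paths share only the coefficient
    bookkeeping, not the transform.
    """
    hkl, F = _as_coeffs(coeffs)
    dims = tuple(grid)
    cgrid = _coefficient_grid(hkl, F, dims, f000)
    idx = np.argwhere(cgrid != 0)
    vals = cgrid[tuple(idx.T)]
    # map index back to signed h for the exponential (value is mod-n agnostic,
    # since exp(-2pi i h j / n) depends only on h mod n)
    xa = np.arange(dims[0]) / dims[0]
    xb = np.arange(dims[1]) / dims[1]
    xc = np.arange(dims[2]) / dims[2]
    rho = np.zeros(dims, dtype=complex)
    for (h, k, l), f in zip(idx, vals):
        pa = np.exp(-2j * np.pi * h * xa)[:, None, None]
        pb = np.exp(-2j * np.pi * k * xb)[None, :, None]
        pc = np.exp(-2j * np.pi * l * xc)[None, None, :]
        rho += f * pa * pb * pc
    return DensityMap(values=rho.real / cell.volume, cell=cell, scale_state="absolute")


def sigma_scale(dmap: DensityMap) -> DensityMap:
    """Replace values by (value - mean)/rms; idempotent on sigma-scaled maps."""
    rms = dmap.rms
    if rms <= 0:
        raise ValueError("cannot sigma-scale a flat map")
    return DensityMap(
        values=(dmap.values - dmap.mean) / rms,
        cell=dmap.cell,
        scale_state="sigma",
        d_min=dmap.d_min,
    )


def difference_map(
    light_scaled: AmplitudeSet,
    dark: AmplitudeSet,
    dark_phases: ComplexSFSet,
    d_min: float,
    cell: UnitCell | None = None,
) -> DensityMap:
    """Fo-Fo difference Fourier map.

    Synthesizes (F_light - F_dark) exp(i Phi_calc) over the shared indices and
    returns the map sigma-scaled.  The light set must already be on the dark
    scale.  Raises with the missing indices if the sets do not share indices.
    """
    il, id_ = light_scaled.common_with(dark)
    if len(il) < len(light_scaled) or len(il) < len(dark):
        missing = set(map(tuple, light_scaled.hkl.tolist())) ^ set(map(tuple, dark.hkl.tolist()))
        raise ValueError(f"index mismatch between light and dark sets: {sorted(missing)[:10]}")
    diff = AmplitudeSet(
        hkl=light_scaled.hkl[il],
        F=light_scaled.F[il] - dark.F[id_],
        sigF=np.sqrt(light_scaled.sigF[il] ** 2 + dark.sigF[id_] ** 2),
        label="Fo-Fo",
        signed=True,
    )
    pm = dark_phases.index_map()
    lacking = [t for t in map(tuple, diff.hkl.tolist()) if t not in pm]
    if lacking:
        raise ValueError(f"phase set missing indices: {lacking[:10]}")
    cell = cell or cell_of(light_scaled, dark)
    dmap = synthesize_map((diff, dark_phases), cell, d_min)
    return sigma_scale(dmap)


def cell_of(*objs) -> UnitCell:
    """First unit cell found attached to the arguments (``.cell`` attribute or
    ``meta['cell']`` of an amplitude set)."""
    for o in objs:
        cell = getattr(o, "cell", None)
        if not isinstance(cell, UnitCell) and hasattr(o, "meta"):
            cell = o.meta.get("cell")
        if isinstance(cell, UnitCell):
            return cell
    raise ValueError("no unit cell attached to any argument; pass cell= explicitly")


def find_peaks(
    dmap: DensityMap,
    threshold: float,
    model: AtomicModel | None = None,
) -> list[MapPeak]:
    """Signed local extrema of a sigma-scaled map with |height| >= threshold.

    26-neighbour extremum test on the periodic grid; each peak is annotated
    with the nearest atom of ``model`` (minimum-image distance).  Sorted by
    |height| descending, ties by lexicographic grid index.
    """
    if dmap.scale_state != "sigma":
        raise ValueError("peak search expects a sigma-scaled map")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    v = dmap.values
    mx = ndimage.maximum_filter(v, size=3, mode="wrap")
    mn = ndimage.minimum_filter(v, size=3, mode="wrap")
    pos = np.argwhere((v == mx) & (v >= threshold))
    neg = np.argwhere((v == mn) & (v <= -threshold))
    n = np.asarray(v.shape)
    peaks: list[tuple[float, tuple[int, ...], float]] = []
    for idx in pos:
        peaks.append((-v[tuple(idx)], tuple(idx), v[tuple(idx)]))
    for idx in neg:
        peaks.append((v[tuple(idx)], tuple(idx), v[tuple(idx)]))
    # sort key: |height| descending then lexicographic grid index
    peaks.sort(key=lambda t: (-abs(t[2]), t[1]))
    out = []
    for _, idx, height in peaks:
        frac = np.asarray(idx) / n
        name, dist = ("", float("nan"))
        if model is not None:
            name, dist = _nearest_atom(frac, model)
        out.append(MapPeak(frac=tuple(frac), height=float(height), nearest_atom=name, distance=dist))
    return out


def _nearest_atom(frac: np.ndarray, model: AtomicModel) -> tuple[str, float]:
    d = model.frac - frac[None, :]
    d -= np.rint(d)                       # minimum image in fractional space
    cart = d @ model.cell.orth_matrix.T
    dist = np.linalg.norm(cart, axis=1)
    j = int(np.argmin(dist))
    return model.names[j], float(dist[j])


# --------------------------------------------------------------------------
# CCP4/MRC map I/O (mode 2, via gemmi)
# --------------------------------------------------------------------------

def write_ccp4(dmap: DensityMap, path: str) -> None:
    """Write a standard CCP4/MRC mode-2 (32-bit real) map file."""
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values, dtype=np.float32))
    c = dmap.cell
    m.grid.unit_cell = gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header(2)
    m.write_ccp4_map(path)


def read_ccp4(path: str) -> DensityMap:
    """Read a CCP4/MRC map back into a :class:`DensityMap`.

    The magic word is checked explicitly so a malformed header fails with the
    name of the offending header word.
    """
    with open(path, "rb") as fh:
        header = fh.read(212)
    if len(header) < 212 or header[208:212] != b"MAP ":
        raise ValueError("malformed CCP4 header: bad MAP magic word at byte 208")
    import gemmi

    m = gemmi.read_ccp4_map(path)
    c = m.grid.unit_cell
    return DensityMap(
        values=np.array(m.grid, copy=True).astype(float),
        cell=UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma),
        scale_state="absolute",
    )
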