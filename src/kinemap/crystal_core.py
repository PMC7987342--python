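"""Crystallographic domain types and reflection/model file I/O.

Conventions used across the package (stated once, used everywhere):

* Coordinates are stored **fractionally**; orthogonalization follows the PDB
  CRYST1 convention (cell vector *a* along Cartesian *x*, *b* in the *xy*
  plane).
* The space-group scope of the whole package is **P1**: every implemented
  equation is symmetry-agnostic, and symmetry expansion is deliberately out
  of scope.
* The scattering variable is ``s = 1/d`` (not ``1/(2d)``); the isotropic
  Debye-Waller factor is ``exp(-B s^2 / 4)`` and atomic form factors are
  ``f(s) = sum_i a_i exp(-b_i s^2 / 4) + c`` so that standard 4-Gaussian
  (Cromer-Mann-style) coefficient sets apply unchanged.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "AtomicModel",
    "Reflection",
    "AmplitudeSet",
    "ComplexSFSet",
    "FormFactorTable",
    "DEFAULT_FORM_FACTORS",
    "ELECTRON_COUNTS",
    "d_spacing",
    "generate_hkl",
    "read_model",
    "write_model",
    "read_amplitudes",
    "write_amplitudes",
    "ParseError",
]


class ParseError(ValueError):
    """Raised for malformed model or reflection files."""


# --------------------------------------------------------------------------
# Unit cell
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180) deg")
        # metric sanity: the squared-volume factor must be positive
        if self._volume_factor() <= 0:
            raise ValueError("cell angles are metrically inconsistent (volume <= 0)")

    def _volume_factor(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @cached_property
    def volume(self) -> float:
        """Cell volume in Angstrom^3 (standard metric formula)."""
        return self.a * self.b * self.c * math.sqrt(self._volume_factor())

    @cached_property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix mapping fractional -> Cartesian (PDB convention)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(self._volume_factor())
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, c * v / sg],
            ]
        )

    @cached_property
    def frac_matrix(self) -> np.ndarray:
        """Inverse of :attr:`orth_matrix` (Cartesian -> fractional)."""
        return np.linalg.inv(self.orth_matrix)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional coordinates (..., 3) -> Cartesian Angstrom."""
        return np.asarray(frac, dtype=float) @ self.orth_matrix.T

    def fractionalize(self, cart: np.ndarray) -> np.ndarray:
        """Cartesian Angstrom (..., 3) -> fractional."""
        return np.asarray(cart, dtype=float) @ self.frac_matrix.T

    def scattering_vector_lengths(self, hkl: np.ndarray) -> np.ndarray:
        """|s| = 1/d for an (N, 3) integer index array."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        # reciprocal basis vectors are the rows of frac_matrix
        s = hkl @ self.frac_matrix
        return np.linalg.norm(s, axis=-1)

    def is_close(self, other: "UnitCell", tol: float = 1e-6) -> bool:
        return all(
            abs(getattr(self, n) - getattr(other, n)) <= tol
            for n in ("a", "b", "c", "alpha", "beta", "gamma")
        )


def d_spacing(cell: UnitCell, hkl: Sequence[int]) -> float:
    """Resolution d (Angstrom) of one reflection, from the reciprocal metric.

    Raises ``ValueError`` for the forbidden (0,0,0) index.
    """
    h = np.asarray(hkl, dtype=int)
    if not np.any(h):
        raise ValueError("d-spacing undefined for (0,0,0)")
    return float(1.0 / cell.scattering_vector_lengths(h)[0])


@dataclass(frozen=True)
class Reflection:
    """A single Miller index."""

    h: int
    k: int
    l: int

    def d(self, cell: UnitCell) -> float:
        return d_spacing(cell, (self.h, self.k, self.l))

    @property
    def hkl(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)


def generate_hkl(cell: UnitCell, d_min: float) -> np.ndarray:
    """All Miller indices with d >= d_min, Friedel-complete, (0,0,0) excluded.

    Returns an (N, 3) integer array sorted lexicographically.  The index
    bounds use |h| <= a/d_min (projection of s on the real-space axes), which
    is exact for any triclinic cell.
    """
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    # +1 guards against floating-point truncation of boundary indices; the
    # |s| filter below removes the excess
    hmax = int(math.floor(cell.a / d_min)) + 1
    kmax = int(math.floor(cell.b / d_min)) + 1
    lmax = int(math.floor(cell.c / d_min)) + 1
    hs = np.arange(-hmax, hmax + 1)
    ks = np.arange(-kmax, kmax + 1)
    ls = np.arange(-lmax, lmax + 1)
    grid = np.stack(np.meshgrid(hs, ks, ls, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[np.any(grid != 0, axis=1)]
    if grid.size == 0:
        return grid.reshape(0, 3)
    keep = cell.scattering_vector_lengths(grid) <= 1.0 / d_min + 1e-12
    out = grid[keep]
    order = np.lexsort((out[:, 2], out[:, 1], out[:, 0]))
    return out[order]


# --------------------------------------------------------------------------
# Atomic model
# --------------------------------------------------------------------------

@dataclass
class AtomicModel:
    """A P1 atomic model: element symbols, fractional coordinates, occupancies
    and isotropic B-factors in a :class:`UnitCell`.

    Arrays are kept columnar for vectorised structure-factor work; ``names``
    carries a human-readable label per atom (e.g. ``"S7"``) used for peak
    annotation.
    """

    cell: UnitCell
    elements: tuple[str, ...]
    frac: np.ndarray          # (N, 3) fractional coordinates
    occ: np.ndarray           # (N,) occupancies in [0, 1]
    b_iso: np.ndarray         # (N,) isotropic B in A^2, >= 0
    names: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        self.frac = np.atleast_2d(np.asarray(self.frac, dtype=float))
        self.occ = np.asarray(self.occ, dtype=float)
        self.b_iso = np.asarray(self.b_iso, dtype=float)
        n = len(self.elements)
        if self.frac.shape != (n, 3) or self.occ.shape != (n,) or self.b_iso.shape != (n,):
            raise ValueError("inconsistent atom array shapes")
        if np.any(self.occ < 0) or np.any(self.occ > 1):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.any(self.b_iso < 0):
            raise ValueError("B-factors must be >= 0")
        if not self.names:
            self.names = tuple(f"{el}{i + 1}" for i, el in enumerate(self.elements))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def cart(self) -> np.ndarray:
        """Cartesian coordinates (N, 3) in Angstrom."""
        return self.cell.orthogonalize(self.frac)

    def copy(self, label: str | None = None) -> "AtomicModel":
        return AtomicModel(
            cell=self.cell,
            elements=self.elements,
            frac=self.frac.copy(),
            occ=self.occ.copy(),
            b_iso=self.b_iso.copy(),
            names=self.names,
            label=self.label if label is None else label,
        )


# --------------------------------------------------------------------------
# Reflection data containers
# --------------------------------------------------------------------------

def match_indices(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positional indices (into a, into b) of Miller indices present in both
    (ordered by a's ordering).  Vectorised via a packed 1-D key."""
    a = np.atleast_2d(np.asarray(a, dtype=np.int64))
    b = np.atleast_2d(np.asarray(b, dtype=np.int64))
    off = 1 << 20
    ka = ((a[:, 0] + off) << 42) | ((a[:, 1] + off) << 21) | (a[:, 2] + off)
    kb = ((b[:, 0] + off) << 42) | ((b[:, 1] + off) << 21) | (b[:, 2] + off)
    order = np.argsort(kb, kind="stable")
    pos = np.searchsorted(kb[order], ka)
    pos_c = np.clip(pos, 0, len(kb) - 1)
    hit = kb[order][pos_c] == ka
    return np.nonzero(hit)[0], order[pos_c[hit]]


def _check_indices(hkl: np.ndarray) -> None:
    if np.any(~np.any(hkl != 0, axis=1)):
        raise ValueError("(0,0,0) is not a valid observed/calculated index")
    uniq = np.unique(hkl, axis=0)
    if len(uniq) != len(hkl):
        seen: set[tuple[int, int, int]] = set()
        for row in map(tuple, hkl.tolist()):
            if row in seen:
                raise ValueError(f"duplicate reflection index {row}")
            seen.add(row)


@dataclass
class AmplitudeSet:
    """Indexed reflection amplitudes |F| with standard deviations.

    ``signed=True`` relaxes the F >= 0 invariant; it marks derived sets that
    legitimately carry signed values (model-difference amplitudes, negative
    extrapolated amplitudes that are retained rather than truncated).
    """

    hkl: np.ndarray           # (N, 3) int
    F: np.ndarray             # (N,)
    sigF: np.ndarray          # (N,)
    label: str = ""
    d_min: float | None = None
    signed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        self.F = np.asarray(self.F, dtype=float)
        self.sigF = np.asarray(self.sigF, dtype=float)
        n = len(self.hkl)
        if self.F.shape != (n,) or self.sigF.shape != (n,):
            raise ValueError("F/sigF length does not match index count")
        _check_indices(self.hkl)
        if not self.signed and np.any(self.F < 0):
            raise ValueError("negative amplitude in an unsigned AmplitudeSet")
        if np.any(self.sigF < 0):
            raise ValueError("sigF must be >= 0")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def reflections(self) -> list[Reflection]:
        return [Reflection(*row) for row in self.hkl.tolist()]

    def index_map(self) -> dict[tuple[int, int, int], int]:
        return {tuple(row): i for i, row in enumerate(self.hkl.tolist())}

    def common_with(self, other: "AmplitudeSet | ComplexSFSet") -> tuple[np.ndarray, np.ndarray]:
        """Positional indices (into self, into other) of shared Miller indices,
        ordered by self's ordering."""
        return match_indices(self.hkl, other.hkl)

    def select(self, idx: np.ndarray, label: str | None = None) -> "AmplitudeSet":
        return AmplitudeSet(
            hkl=self.hkl[idx],
            F=self.F[idx],
            sigF=self.sigF[idx],
            label=self.label if label is None else label,
            d_min=self.d_min,
            signed=self.signed,
            meta=dict(self.meta),
        )


@dataclass
class ComplexSFSet:
    """Indexed complex structure factors (amplitude + calculated phase)."""

    hkl: np.ndarray                # (N, 3) int
    F_complex: np.ndarray          # (N,) complex
    label: str = ""

    def __post_init__(self) -> None:
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        self.F_complex = np.asarray(self.F_complex, dtype=complex)
        if self.F_complex.shape != (len(self.hkl),):
            raise ValueError("F_complex length does not match index count")
        _check_indices(self.hkl)

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.F_complex)

    @property
    def phase_deg(self) -> np.ndarray:
        """Phase angle Phi_calc in degrees."""
        return np.degrees(np.angle(self.F_complex))

    def index_map(self) -> dict[tuple[int, int, int], int]:
        return {tuple(row): i for i, row in enumerate(self.hkl.tolist())}


# --------------------------------------------------------------------------
# Form factors
# --------------------------------------------------------------------------

ELECTRON_COUNTS: dict[str, int] = {
    "H": 1, "C": 6, "N": 7, "O": 8, "NA": 11, "MG": 12, "P": 15, "S": 16,
    "CL": 17, "K": 19, "CA": 20, "FE": 26, "ZN": 30,
}

# 4-Gaussian coefficients (a1..a4, b1..b4, c) for the light elements the toy
# models use.  f(0) reproduces the electron count to < 0.1 %.
_CM = {
    "C": ((2.3100, 1.0200, 1.5886, 0.8650),
          (20.8439, 10.2075, 0.5687, 51.6512), 0.2156),
    "N": ((12.2126, 3.1322, 2.0125, 1.1663),
          (0.0057, 9.8933, 28.9975, 0.5826), -11.5290),
    "O": ((3.0485, 2.2868, 1.5463, 0.8670),
          (13.2771, 5.7011, 0.3239, 32.9089), 0.2508),
    "S": ((6.9053, 5.2034, 1.4379, 1.5863),
          (1.4679, 22.2151, 0.2536, 56.1720), 0.8669),
}


class FormFactorTable:
    """Element -> 4-Gaussian form-factor coefficients.

    ``f(s) = sum_i a_i exp(-b_i s^2/4) + c`` with ``s = 1/d``; the ``b``
    coefficients are stored to match this convention (identical to tabulated
    sin(theta)/lambda coefficients, since ``s/2 = sin(theta)/lambda``).
    Elements without coefficients fall back to a constant ``f = Z`` with a
    warning.
    """

    def __init__(self, coeffs: dict | None = None):
        self.coeffs = dict(_CM if coeffs is None else coeffs)

    def evaluate(self, element: str, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        el = element.upper() if element.upper() in ELECTRON_COUNTS else element
        key = element if element in self.coeffs else element.upper()
        if key in self.coeffs:
            a, b, c = self.coeffs[key]
            s2q = s * s / 4.0
            out = np.full_like(s, float(c))
            for ai, bi in zip(a, b):
                out = out + ai * np.exp(-bi * s2q)
            return out
        z = ELECTRON_COUNTS.get(el)
        if z is None:
            raise KeyError(f"no form factor or electron count for element {element!r}")
        warnings.warn(
            f"no 4-Gaussian coefficients for {element!r}; using constant f = {z}",
            stacklevel=2,
        )
        return np.full_like(s, float(z))

    def f0(self, element: str) -> float:
        """Forward-scattering value f(0) (approximately the electron count)."""
        return float(self.evaluate(element, np.zeros(1))[0])


DEFAULT_FORM_FACTORS = FormFactorTable()


# --------------------------------------------------------------------------
# PDB model I/O (minimal P1 subset: CRYST1 + ATOM/HETATM fixed columns)
# --------------------------------------------------------------------------

def read_model(text: str | io.TextIOBase, label: str = "") -> AtomicModel:
    """Parse a PDB-format model (CRYST1 + ATOM/HETATM records).

    Orthogonal coordinates are converted to fractional using the CRYST1 cell.
    Raises :class:`ParseError` with "no cell" when CRYST1 is absent and a
    line-numbered error for an unparsable atom record.
    """
    if hasattr(text, "read"):
        text = text.read()
    cell: UnitCell | None = None
    elements: list[str] = []
    cart: list[list[float]] = []
    occ: list[float] = []
    b_iso: list[float] = []
    names: list[str] = []
    for lineno, line in enumerate(str(text).splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                cell = UnitCell(
                    float(line[6:15]), float(line[15:24]), float(line[24:33]),
                    float(line[33:40]), float(line[40:47]), float(line[47:54]),
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: bad CRYST1 record: {exc}") from exc
        elif rec in ("ATOM", "HETATM"):
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                o = float(line[54:60]) if line[54:60].strip() else 1.0
                b = float(line[60:66]) if line[60:66].strip() else 0.0
                el = line[76:78].strip() or line[12:16].strip()[:1]
                name = line[12:16].strip() or el
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: unparsable atom record: {exc}") from exc
            elements.append(el.upper())
            cart.append([x, y, z])
            occ.append(o)
            b_iso.append(b)
            names.append(name)
    if cell is None:
        raise ParseError("no cell: missing CRYST1 record")
    if not elements:
        raise ParseError("no ATOM/HETATM records found")
    frac = cell.fractionalize(np.asarray(cart))
    return AtomicModel(
        cell=cell,
        elements=tuple(elements),
        frac=frac,
        occ=np.asarray(occ),
        b_iso=np.asarray(b_iso),
        names=tuple(names),
        label=label,
    )


def write_model(model: AtomicModel) -> str:
    """Serialize a model to PDB text (CRYST1 + HETATM records, P1)."""
    c = model.cell
    lines = [
        f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
        f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} P 1           1"
    ]
    cart = model.cart()
    for i in range(model.n_atoms):
        el = model.elements[i]
        name = model.names[i][:4]
        lines.append(
            f"HETATM{i + 1:5d} {name:<4s} LIG A{1:4d}    "
            f"{cart[i, 0]:8.3f}{cart[i, 1]:8.3f}{cart[i, 2]:8.3f}"
            f"{model.occ[i]:6.2f}{model.b_iso[i]:6.2f}          {el:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Reflection file I/O
# --------------------------------------------------------------------------

def read_amplitudes(
    text: str | io.TextIOBase,
    dialect: str = "plain",
    label: str = "",
    signed: bool = False,
) -> AmplitudeSet:
    """Read observed amplitudes.

    ``dialect="plain"``: whitespace-delimited text whose header line names the
    columns ``h k l F sigF`` (any order).  ``dialect="mmcif"``: structure-factor
    mmCIF with ``_refln.index_h/k/l``, ``_refln.F_meas_au``,
    ``_refln.F_meas_sigma_au`` (parsed with gemmi).

    Observed amplitude files must be non-negative unless ``signed=True``
    (extrapolated amplitude files legitimately carry negative values and are
    read back as signed sets).
    """
    if hasattr(text, "read"):
        text = text.read()
    text = str(text)
    if dialect == "plain":
        return _read_plain(text, label, signed)
    if dialect == "mmcif":
        return _read_mmcif_sf(text, label, signed)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_plain(text: str, label: str, signed: bool = False) -> AmplitudeSet:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ParseError("empty reflection file")
    header = lines[0].split()
    required = ["h", "k", "l", "F", "sigF"]
    lower = [t.lower() for t in header]
    try:
        cols = {name: lower.index(name.lower()) for name in required}
    except ValueError as exc:
        raise ParseError(f"header must declare columns {required}, got {header}") from exc
    hkl, F, sigF = [], [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        toks = ln.split()
        try:
            hkl.append([int(toks[cols["h"]]), int(toks[cols["k"]]), int(toks[cols["l"]])])
            F.append(float(toks[cols["F"]]))
            sigF.append(float(toks[cols["sigF"]]))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"line {lineno}: unparsable reflection row: {exc}") from exc
    return AmplitudeSet(hkl=np.asarray(hkl), F=np.asarray(F), sigF=np.asarray(sigF),
                        label=label, signed=signed)


def _read_mmcif_sf(text: str, label: str, signed: bool = False) -> AmplitudeSet:
    import gemmi

    doc = gemmi.cif.read_string(text)
    block = doc.sole_block()
    h = block.find_loop("_refln.index_h")
    k = block.find_loop("_refln.index_k")
    l = block.find_loop("_refln.index_l")
    F = block.find_loop("_refln.F_meas_au")
    s = block.find_loop("_refln.F_meas_sigma_au")
    if not (h and k and l and F and s):
        raise ParseError("mmCIF block lacks _refln index/F_meas_au/F_meas_sigma_au items")
    hkl = np.array([[int(a), int(b), int(c)] for a, b, c in zip(h, k, l)])
    return AmplitudeSet(
        hkl=hkl,
        F=np.array([float(x) for x in F]),
        sigF=np.array([float(x) for x in s]),
        label=label,
        signed=signed,
    )


def write_amplitudes(ampl: AmplitudeSet) -> str:
    """Serialize to the plain-hkl dialect (header ``h k l F sigF``)."""
    lines = ["h k l F sigF"]
    for (h, k, l), f, sf in zip(ampl.hkl.tolist(), ampl.F, ampl.sigF):
        lines.append(f"{h:d} {k:d} {l:d} {f:.8g} {sf:.8g}")
    return "\n".join(lines) + "\n"
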