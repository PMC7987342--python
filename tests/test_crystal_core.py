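"""Unit cells, models, reflection generation and file I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinemap.crystal_core import (
    AmplitudeSet,
    DEFAULT_FORM_FACTORS,
    FormFactorTable,
    ParseError,
    UnitCell,
    d_spacing,
    generate_hkl,
    match_indices,
    read_amplitudes,
    read_model,
    write_amplitudes,
    write_model,
)

MINIMAL_PDB = """\
CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1           1
ATOM      1  C   LIG A   1       5.000   0.000   0.000  1.00 10.00           C
END
"""


def brute_force_d(cell, h, k, l):
    """Textbook triclinic d-spacing formula, independent of the metric-tensor
    implementation under test."""
    a, b, c = cell.a, cell.b, cell.c
    al, be, ga = (math.radians(x) for x in (cell.alpha, cell.beta, cell.gamma))
    ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
    sa, sb, sg = math.sin(al), math.sin(be), math.sin(ga)
    V = a * b * c * math.sqrt(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg)
    S11 = (b * c * sa) ** 2
    S22 = (a * c * sb) ** 2
    S33 = (a * b * sg) ** 2
    S12 = a * b * c**2 * (ca * cb - cg)
    S23 = a**2 * b * c * (cb * cg - ca)
    S13 = a * b**2 * c * (cg * ca - cb)
    inv_d2 = (S11 * h**2 + S22 * k**2 + S33 * l**2
              + 2 * S12 * h * k + 2 * S23 * k * l + 2 * S13 * h * l) / V**2
    return 1.0 / math.sqrt(inv_d2)


class TestUnitCell:
    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            UnitCell(-1, 10, 10)
        with pytest.raises(ValueError):
            UnitCell(10, 10, 10, 0.0, 90, 90)
        with pytest.raises(ValueError):
            UnitCell(10, 10, 10, 10, 10, 170)  # metrically impossible

    def test_cubic_volume(self, cubic_cell):
        assert cubic_cell.volume == pytest.approx(1000.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(3, 50), b=st.floats(3, 50), c=st.floats(3, 50),
        alpha=st.floats(70, 110), beta=st.floats(70, 110), gamma=st.floats(70, 110),
        frac=st.lists(st.floats(0, 0.999), min_size=3, max_size=3),
    )
    def test_frac_orth_round_trip(self, a, b, c, alpha, beta, gamma, frac):
        """Fractional -> orthogonal -> fractional is the identity to 1e-10."""
        cell = UnitCell(a, b, c, alpha, beta, gamma)
        x = np.asarray(frac)
        back = cell.fractionalize(cell.orthogonalize(x))
        assert np.allclose(back, x, atol=1e-10)

    def test_orthogonalization_matches_gemmi(self, triclinic_cell):
        import gemmi

        g = gemmi.UnitCell(*[getattr(triclinic_cell, n)
                             for n in ("a", "b", "c", "alpha", "beta", "gamma")])
        x = np.array([0.2, 0.3, 0.7])
        ours = triclinic_cell.orthogonalize(x)
        theirs = g.orthogonalize(gemmi.Fractional(*x))
        assert np.allclose(ours, [theirs.x, theirs.y, theirs.z], atol=1e-8)
        assert triclinic_cell.volume == pytest.approx(g.volume, rel=1e-10)


class TestDSpacing:
    def test_cubic_axis(self, cubic_cell):
        assert d_spacing(cubic_cell, (1, 0, 0)) == pytest.approx(10.0)

    def test_origin_rejected(self, cubic_cell):
        with pytest.raises(ValueError):
            d_spacing(cubic_cell, (0, 0, 0))

    @pytest.mark.parametrize("hkl", [(1, 2, 3), (2, -1, 1), (-3, 0, 2)])
    def test_triclinic_matches_brute_force(self, triclinic_cell, hkl):
        ours = d_spacing(triclinic_cell, hkl)
        ref = brute_force_d(triclinic_cell, *hkl)
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_matches_gemmi(self, triclinic_cell):
        import gemmi

        g = gemmi.UnitCell(7, 8, 9, 80, 95, 100)
        assert d_spacing(triclinic_cell, (1, 2, 3)) == pytest.approx(
            g.calculate_d((1, 2, 3)), rel=1e-10)


class TestGenerateHkl:
    def test_cubic_first_shell(self, cubic_cell):
        hkl = generate_hkl(cubic_cell, 10.0)
        expected = {(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)}
        assert set(map(tuple, hkl.tolist())) == expected

    def test_too_coarse_is_empty(self, cubic_cell):
        assert len(generate_hkl(cubic_cell, 11.0)) == 0

    def test_friedel_complete(self, triclinic_cell):
        hkl = set(map(tuple, generate_hkl(triclinic_cell, 2.0).tolist()))
        assert all((-h, -k, -l) in hkl for h, k, l in hkl)

    @settings(max_examples=20, derandomize=True)
    @given(a=st.floats(5, 30), ratio=st.floats(0.1, 0.9))
    def test_count_matches_brute_force_cubic(self, a, ratio):
        """Reflection count equals enumeration of the full bounding index box."""
        cell = UnitCell(a, a, a)
        d_min = a * ratio
        got = len(generate_hkl(cell, d_min))
        m = int(math.floor(a / d_min)) + 2
        count = 0
        for h in range(-m, m + 1):
            for k in range(-m, m + 1):
                for l in range(-m, m + 1):
                    if (h, k, l) == (0, 0, 0):
                        continue
                    # same boundary convention as the implementation
                    if math.sqrt(h * h + k * k + l * l) / a <= 1.0 / d_min + 1e-12:
                        count += 1
        assert got == count


class TestModelIO:
    def test_minimal_pdb(self):
        model = read_model(MINIMAL_PDB)
        assert model.n_atoms == 1
        assert model.elements == ("C",)
        assert np.allclose(model.frac[0], [0.5, 0.0, 0.0])

    def test_missing_cryst1(self):
        with pytest.raises(ParseError, match="no cell"):
            read_model("HEADER    TEST\nEND\n")

    def test_bad_atom_line_is_line_numbered(self):
        bad = MINIMAL_PDB.replace("5.000", "fivex")
        with pytest.raises(ParseError, match="line 2"):
            read_model(bad)

    def test_round_trip_toy_model(self, toy_pair):
        dark, _ = toy_pair
        back = read_model(write_model(dark))
        assert back.cell.is_close(dark.cell, tol=1e-3)
        # written coordinates carry 3 decimals in Angstrom
        assert np.allclose(back.frac, dark.frac % 1.0, atol=1e-4)
        assert back.elements == dark.elements
        assert np.allclose(back.b_iso, dark.b_iso, atol=1e-2)

    def test_written_pdb_readable_by_gemmi(self, toy_pair):
        import gemmi

        dark, _ = toy_pair
        st_ = gemmi.read_pdb_string(write_model(dark))
        atoms = [a for model in st_ for chain in model for res in chain for a in res]
        assert len(atoms) == dark.n_atoms
        ours = dark.cart()
        theirs = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
        # same order by construction
        assert np.allclose(np.sort(ours.ravel()), np.sort(theirs.ravel()), atol=1e-3)


class TestAmplitudeIO:
    def test_plain_round_trip_small(self):
        text = "h k l F sigF\n1 0 0 12.5 0.3\n0 1 0 8.25 0.2\n2 1 -1 3.5 0.1\n"
        s = read_amplitudes(text)
        assert len(s) == 3
        assert s.F[0] == 12.5 and s.sigF[2] == 0.1
        again = read_amplitudes(write_amplitudes(s))
        assert np.array_equal(again.hkl, s.hkl)
        assert np.allclose(again.F, s.F, atol=1e-6)

    def test_duplicate_index_rejected(self):
        text = "h k l F sigF\n1 0 0 12.5 0.3\n1 0 0 8.0 0.2\n"
        with pytest.raises(ValueError, match=r"\(1, 0, 0\)"):
            read_amplitudes(text)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            read_amplitudes("h k l F sigF\n1 0 0 -1.0 0.3\n")

    def test_large_round_trip(self, mixed_obs):
        dark_obs, _ = mixed_obs
        sub = dark_obs.select(np.arange(500))
        back = read_amplitudes(write_amplitudes(sub))
        assert np.max(np.abs(back.F - sub.F)) <= 1e-6

    def test_mmcif_dialect(self):
        cif = """\
data_test
loop_
_refln.index_h
_refln.index_k
_refln.index_l
_refln.F_meas_au
_refln.F_meas_sigma_au
1 0 0 12.5 0.3
0 1 0 8.25 0.2
"""
        s = read_amplitudes(cif, dialect="mmcif")
        assert len(s) == 2
        assert s.F[1] == pytest.approx(8.25)


class TestMatchIndices:
    def test_partial_overlap(self):
        a = np.array([[1, 0, 0], [0, 1, 0], [2, 2, 2]])
        b = np.array([[0, 1, 0], [1, 0, 0], [3, 3, 3]])
        ia, ib = match_indices(a, b)
        assert [tuple(a[i]) for i in ia] == [(1, 0, 0), (0, 1, 0)]
        assert [tuple(b[i]) for i in ib] == [(1, 0, 0), (0, 1, 0)]


class TestFormFactors:
    @pytest.mark.parametrize("el,z", [("C", 6), ("N", 7), ("O", 8), ("S", 16)])
    def test_f0_is_electron_count(self, el, z):
        assert DEFAULT_FORM_FACTORS.f0(el) == pytest.approx(z, rel=0.02)

    def test_unknown_element_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            f = DEFAULT_FORM_FACTORS.evaluate("P", np.array([0.0, 0.5]))
        assert np.allclose(f, 15.0)

    def test_form_factor_decreases_with_resolution(self):
        s = np.linspace(0, 1.5, 10)
        f = DEFAULT_FORM_FACTORS.evaluate("C", s)
        assert np.all(np.diff(f) < 0)
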