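import numpy as np
import pytest

from kinemap.crystal_core import UnitCell
from kinemap.synthetic_data import make_toy_crystal_pair, simulate_tr_reflections


@pytest.fixture(scope="session")
def cubic_cell():
    return UnitCell(10.0, 10.0, 10.0)


@pytest.fixture(scope="session")
def triclinic_cell():
    return UnitCell(7.0, 8.0, 9.0, 80.0, 95.0, 100.0)


@pytest.fixture(scope="session")
def toy_pair():
    """Deterministic dark/light toy crystal pair (seed 0)."""
    return make_toy_crystal_pair(0)


@pytest.fixture(scope="session")
def mixed_obs(toy_pair):
    """Noiseless observed amplitude pair for a 30% activation mixture."""
    dark, light = toy_pair
    return simulate_tr_reflections(dark, light, R_true=0.30, noise_frac=0.0,
                                   seed=100, d_min=1.8)


def random_coefficients(rng, cell, n=50, hmax=4):
    """Random Friedel-complete complex coefficient set for map tests."""
    from kinemap.crystal_core import ComplexSFSet

    seen = set()
    rows, vals = [], []
    while len(rows) < 2 * n:
        h = tuple(int(x) for x in rng.integers(-hmax, hmax + 1, size=3))
        if h == (0, 0, 0) or h in seen:
            continue
        mate = tuple(-x for x in h)
        f = rng.normal() + 1j * rng.normal()
        seen.update({h, mate})
        rows.extend([h, mate])
        vals.extend([f, np.conj(f)])
    return ComplexSFSet(hkl=np.array(rows), F_complex=np.array(vals))
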