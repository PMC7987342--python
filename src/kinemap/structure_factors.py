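"""Direct-summation structure-factor calculation.

The package computes calculated structure factors by explicit summation over
atoms,

    F(h) = sum_j occ_j * f_j(s) * exp(-B_j s^2 / 4) * exp(2 pi i h . x_j),

with s = 1/d.  Toy models are small (<= ~100 atoms), so the O(atoms x
reflections) cost is negligible and the direct sum doubles as the package's
ground truth for map synthesis.  No bulk-solvent correction, no anomalous
scattering, no resolution-dependent scaling.
"""

from __future__ import annotations

import numpy as np

from .crystal_core import (
    AmplitudeSet,
    AtomicModel,
    ComplexSFSet,
    DEFAULT_FORM_FACTORS,
    FormFactorTable,
)

__all__ = ["calc_fc", "fc_difference_amplitudes"]


def calc_fc(
    model: AtomicModel,
    hkls: np.ndarray,
    table: FormFactorTable | None = None,
) -> ComplexSFSet:
    """Calculated complex structure factors of ``model`` at the given indices.

    Parameters
    ----------
    model:
        P1 atomic model (fractional coordinates, occupancies, isotropic B).
    hkls:
        (N, 3) integer Miller indices.
    table:
        Form-factor table; defaults to the bundled C/N/O/S 4-Gaussian set.
    """
    if model.n_atoms == 0:
        raise ValueError("cannot compute structure factors of an empty model")
    table = table or DEFAULT_FORM_FACTORS
    hkls = np.atleast_2d(np.asarray(hkls, dtype=int))
    s = model.cell.scattering_vector_lengths(hkls)          # (N,)
    s2q = s * s / 4.0

    # per-atom scattering power at each reflection: f_el(s) * occ * DW
    fa = np.empty((len(hkls), model.n_atoms))
    for el in set(model.elements):
        f_el = table.evaluate(el, s)
        for j, ej in enumerate(model.elements):
            if ej == el:
                fa[:, j] = f_el
    fa *= model.occ[None, :]
    fa *= np.exp(-np.outer(s2q, model.b_iso))

    phase = np.exp(2j * np.pi * (hkls @ model.frac.T))       # (N, n_atoms)
    F = (fa * phase).sum(axis=1)
    return ComplexSFSet(hkl=hkls, F_complex=F, label=model.label)


def fc_difference_amplitudes(
    model_light: AtomicModel,
    model_dark: AtomicModel,
    hkls: np.ndarray,
    table: FormFactorTable | None = None,
) -> AmplitudeSet:
    """Signed model-vs-model amplitude differences |Fc_light| - |Fc_dark|.

    The returned set pairs naturally with the dark model's calculated phases
    for difference-map synthesis.  Both models must share the same cell.
    """
    if not model_light.cell.is_close(model_dark.cell):
        raise ValueError("models have different unit cells")
    fl = calc_fc(model_light, hkls, table)
    fd = calc_fc(model_dark, hkls, table)
    diff = fl.amplitude - fd.amplitude
    return AmplitudeSet(
        hkl=fl.hkl,
        F=diff,
        sigF=np.zeros_like(diff),
        label=f"|Fc_{model_light.label or 'light'}|-|Fc_{model_dark.label or 'dark'}|",
        signed=True,
    )
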