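"""Relative scaling of two observed amplitude sets (light onto dark).

Before amplitude differencing or extrapolation the light data set must sit on
the scale of the dark reference.  The model is the usual isotropic k/B form

    F_dark ~ k * exp(-B_rel * s^2 / 4) * F_light,

fit by weighted least squares over the common reflections with weights
w = 1 / (sig_dark^2 + sig_light^2) (unit weights when sigmas are all zero).
A log-linear regression of ln(F_dark/F_light) against s^2 seeds a nonlinear
refinement; exponential fitting in k and B_rel is otherwise well behaved.
Anisotropic or resolution-bin-local scaling is a documented non-goal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .crystal_core import AmplitudeSet, UnitCell

__all__ = ["ScaleResult", "fit_scale", "apply_scale"]


@dataclass(frozen=True)
class ScaleResult:
    """Fitted linear scale k (> 0), relative isotropic B (A^2), the number of
    common reflections used and the weighted RMS residual after scaling."""

    k: float
    B_rel: float
    n_common: int
    residual: float

    def factors(self, s: np.ndarray) -> np.ndarray:
        """Multiplicative factor k * exp(-B_rel s^2/4) at each |s| = 1/d."""
        s = np.asarray(s, dtype=float)
        return self.k * np.exp(-self.B_rel * s * s / 4.0)


def fit_scale(light: AmplitudeSet, dark: AmplitudeSet, cell: UnitCell) -> ScaleResult:
    """Fit k and B_rel placing ``light`` on the scale of ``dark``.

    Requires >= 2 common reflections.  If the common reflections span a
    negligible range of s^2 (a single resolution shell) B_rel is indeterminate
    and is fixed at 0 with a warning.
    """
    il, id_ = light.common_with(dark)
    if len(il) < 2:
        raise ValueError("need at least 2 reflections common to both sets")
    Fl = light.F[il]
    Fd = dark.F[id_]
    sig2 = light.sigF[il] ** 2 + dark.sigF[id_] ** 2
    w = np.where(sig2 > 0, 1.0 / np.where(sig2 > 0, sig2, 1.0), 1.0)
    if not np.all(sig2 > 0):
        w = np.ones_like(Fl)
    s = cell.scattering_vector_lengths(light.hkl[il])
    s2 = s * s

    # log-linear seed over reflections where both amplitudes are positive
    pos = (Fl > 0) & (Fd > 0)
    span = np.ptp(s2[pos]) if np.any(pos) else 0.0
    single_shell = span < 1e-8 * max(float(np.max(s2)), 1.0)
    if np.count_nonzero(pos) >= 2 and not single_shell:
        slope, intercept = np.polyfit(s2[pos], np.log(Fd[pos] / Fl[pos]), 1)
        k0, b0 = float(np.exp(intercept)), float(-4.0 * slope)
    else:
        k0 = float(np.sum(w * Fd * Fl) / np.sum(w * Fl * Fl))
        b0 = 0.0

    if single_shell:
        warnings.warn("single-resolution-shell data: B_rel fixed at 0", stacklevel=2)
        k = _fit_k_only(Fl, Fd, w)
        resid = _wrms(Fd - k * Fl, w)
        return ScaleResult(k=k, B_rel=0.0, n_common=len(il), residual=resid)

    sw = np.sqrt(w)

    def resid_fn(p: np.ndarray) -> np.ndarray:
        k, b = p
        return sw * (Fd - k * np.exp(-b * s2 / 4.0) * Fl)

    sol = least_squares(resid_fn, x0=[max(k0, 1e-8), b0], method="lm", xtol=1e-14, ftol=1e-14)
    k, b = float(sol.x[0]), float(sol.x[1])
    resid = _wrms(resid_fn(sol.x) / sw, w)
    return ScaleResult(k=k, B_rel=b, n_common=len(il), residual=resid)


def _fit_k_only(Fl: np.ndarray, Fd: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * Fd * Fl) / np.sum(w * Fl * Fl))


def _wrms(r: np.ndarray, w: np.ndarray) -> float:
    return float(np.sqrt(np.sum(w * r * r) / np.sum(w)))


def apply_scale(light: AmplitudeSet, scale: ScaleResult, cell: UnitCell) -> AmplitudeSet:
    """Multiply F and sigF by the fitted k * exp(-B_rel s^2/4) per reflection."""
    s = cell.scattering_vector_lengths(light.hkl)
    fac = scale.factors(s)
    return AmplitudeSet(
        hkl=light.hkl.copy(),
        F=light.F * fac,
        sigF=light.sigF * fac,
        label=f"{light.label or 'light'}_scaled",
        d_min=light.d_min,
        signed=light.signed,
        meta=dict(light.meta),
    )
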