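"""Transient-absorption matrix handling, SVD denoising and global
multi-exponential fitting.

A flash-photolysis experiment produces a matrix ``A`` of absorbance changes
dA(lambda, t) (wavelength rows, delay-time columns).  The analysis chain is:

1. ``A = U S V^T`` (singular values in decreasing order) to judge how many
   spectrally distinct components the data contain;
2. reconstruction from the leading k components to strip random noise;
3. a global fit of the reconstructed matrix with a sum of exponentials whose
   apparent time constants tau_i are shared across all wavelengths, each with
   its decay-associated spectrum (DAS) B_i(lambda), optionally plus a
   non-decaying offset spectrum.

The global fit uses variable projection: the nonlinear search runs only over
log(tau), and at each evaluation the amplitudes are the exact linear
least-squares solution for every wavelength at once.  tau is initialised from
a log-spaced grid over the observed time span (exponential sums are
multimodal), then refined with a Levenberg-Marquardt-style local solver.

Sign convention: dA > 0 means increased absorption after excitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SpectraMatrix",
    "SVDResult",
    "GlobalFitResult",
    "compute_delta_A",
    "svd_decompose",
    "reconstruct",
    "select_rank",
    "global_exp_fit",
    "fit_single_trace",
    "read_spectra_csv",
    "write_spectra_csv",
]


@dataclass
class SpectraMatrix:
    """dA(lambda, t): wavelengths (nm) are rows, delay times (s) columns."""

    wavelengths: np.ndarray
    times: np.ndarray
    dA: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.dA = np.atleast_2d(np.asarray(self.dA, dtype=float))
        if self.dA.shape != (len(self.wavelengths), len(self.times)):
            raise ValueError("dA shape must be (n_wavelengths, n_times)")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class SVDResult:
    """Factorization A = U S V^T with S sorted descending."""

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray              # (n_times, n_components); columns are time vectors
    source: SpectraMatrix
    k: int | None = None

    def reconstruction(self, k: int | None = None) -> np.ndarray:
        kk = len(self.S) if k is None else k
        return (self.U[:, :kk] * self.S[:kk]) @ self.V[:, :kk].T


@dataclass
class GlobalFitResult:
    """Shared time constants with decay-associated spectra."""

    tau: np.ndarray                       # (n_exp,) seconds, ascending
    das: np.ndarray                       # (n_exp, n_wavelengths)
    offset: np.ndarray | None             # (n_wavelengths,) or None
    rms_residual: float
    n_iter: int = 0

    def model(self, times: np.ndarray) -> np.ndarray:
        """Model matrix dA(lambda, t) reconstructed from the fit."""
        times = np.asarray(times, dtype=float)
        out = self.das.T @ np.exp(-times[None, :] / self.tau[:, None])
        if self.offset is not None:
            out = out + self.offset[:, None]
        return out


def compute_delta_A(I_before: np.ndarray, I_after: np.ndarray) -> np.ndarray:
    """Decadic absorbance change dA = -log10(I_after / I_before) per channel."""
    I_before = np.asarray(I_before, dtype=float)
    I_after = np.asarray(I_after, dtype=float)
    if np.any(I_before <= 0) or np.any(I_after <= 0):
        raise ValueError("intensities must be > 0")
    return -np.log10(I_after / I_before)


def svd_decompose(A: SpectraMatrix) -> SVDResult:
    """Full SVD of the dA matrix; numpy returns singular values descending."""
    if A.dA.size == 0:
        raise ValueError("empty matrix")
    U, S, Vt = np.linalg.svd(A.dA, full_matrices=False)
    return SVDResult(U=U, S=S, V=Vt.T, source=A)


def reconstruct(res: SVDResult, k: int) -> SpectraMatrix:
    """Rank-k reconstruction A' = sum_{i<=k} s_i u_i v_i^T."""
    if not 1 <= k <= len(res.S):
        raise ValueError(f"rank k must lie in [1, {len(res.S)}]")
    return SpectraMatrix(
        wavelengths=res.source.wavelengths,
        times=res.source.times,
        dA=res.reconstruction(k),
    )


def select_rank(
    S: np.ndarray,
    n_rows: int,
    n_cols: int,
    noise_estimate: float,
) -> int:
    """Smallest k such that the remaining singular values sit at the noise
    floor of a pure-noise matrix, noise_estimate * (sqrt(n_rows) +
    sqrt(n_cols)) — the bulk edge of the singular-value distribution of an
    i.i.d. Gaussian matrix, which is where the largest *noise* singular value
    concentrates.

    A value of 0 (with a warning) means no component rises above the floor;
    the choice can always be overridden manually, as is common practice when
    judging significant components by eye.
    """
    S = np.asarray(S, dtype=float)
    floor = noise_estimate * (np.sqrt(n_rows) + np.sqrt(n_cols))
    k = 0
    for s in S:                 # leading run above the floor
        if s > floor:
            k += 1
        else:
            break
    if k == 0:
        warnings.warn("no singular value exceeds the noise floor (k = 0)", stacklevel=2)
    return k


def _design_matrix(times: np.ndarray, taus: np.ndarray, offset: bool) -> np.ndarray:
    cols = [np.exp(-times / t) for t in taus]
    if offset:
        cols.append(np.ones_like(times))
    return np.stack(cols, axis=1)


def _projected_residual(
    logtau: np.ndarray, times: np.ndarray, D: np.ndarray, offset: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Residual matrix and coefficients after solving amplitudes linearly."""
    taus = np.exp(np.clip(logtau, -600.0, 600.0))
    Phi = _design_matrix(times, taus, offset)
    C, *_ = np.linalg.lstsq(Phi, D.T, rcond=None)
    R = Phi @ C - D.T
    return R, C


def global_exp_fit(
    A: SpectraMatrix,
    n_exp: int,
    tau_init: np.ndarray | None = None,
    offset: bool = True,
    n_starts: int = 12,
    max_nfev: int = 400,
) -> GlobalFitResult:
    """Global fit dA(lambda, t) = sum_i B_i(lambda) exp(-t/tau_i) [+ offset].

    Time constants are shared across wavelengths; amplitudes are solved
    linearly at every tau evaluation (variable projection).  Without
    ``tau_init`` a log-spaced multi-start grid over [t_min, t_max] seeds the
    local refinement and the best start wins.
    """
    if n_exp < 1:
        raise ValueError("n_exp must be >= 1")
    times, D = A.times, A.dA
    if times.max() <= times.min() and len(times) > 1:
        raise ValueError("times must span a positive interval")
    if not np.any(D):
        taus = np.asarray(tau_init, dtype=float) if tau_init is not None else np.geomspace(
            max(times.min(), 1e-12), times.max(), n_exp + 2)[1:-1]
        nw = len(A.wavelengths)
        return GlobalFitResult(
            tau=np.sort(taus)[:n_exp],
            das=np.zeros((n_exp, nw)),
            offset=np.zeros(nw) if offset else None,
            rms_residual=0.0,
        )

    t_lo = max(float(times[times > 0].min()) if np.any(times > 0) else 1e-9, 1e-12)
    t_hi = float(times.max())
    if tau_init is not None:
        starts = [np.log(np.asarray(tau_init, dtype=float))]
    else:
        rng = np.random.default_rng(0)      # deterministic multi-start jitter
        base = np.linspace(np.log(t_lo), np.log(t_hi), n_exp + 2)[1:-1]
        starts = [base]
        span = np.log(t_hi) - np.log(t_lo)
        for _ in range(n_starts - 1):
            starts.append(
                np.sort(rng.uniform(np.log(t_lo) - 0.5, np.log(t_hi) + 0.5, size=n_exp))
            )
        if n_exp >= 2:
            # include well-separated deterministic grids
            for frac in (0.25, 0.5):
                starts.append(base + np.linspace(-frac * span, frac * span, n_exp))

    best = None
    for x0 in starts:
        sol = least_squares(
            lambda lt: _projected_residual(lt, times, D, offset)[0].ravel(),
            x0=np.asarray(x0, dtype=float),
            method="lm" if D.size > len(x0) else "trf",
            xtol=1e-14,
            ftol=1e-14,
            max_nfev=max_nfev,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    if not best.success and best.cost > 0:
        warnings.warn("exponential fit did not fully converge; returning best point",
                      stacklevel=2)

    taus = np.exp(best.x)
    Rm, C = _projected_residual(best.x, times, D, offset)
    order = np.argsort(taus)
    taus = taus[order]
    das = C[:n_exp][order]
    off = C[n_exp] if offset else None
    for i, j in combinations(range(n_exp), 2):
        if abs(np.log(taus[i] / taus[j])) < 1e-2:
            warnings.warn(
                f"time constants {taus[i]:.3g} and {taus[j]:.3g} are nearly degenerate; "
                "n_exp may exceed the identifiable components",
                stacklevel=2,
            )
            break
    rms = float(np.sqrt(np.mean(Rm**2)))
    return GlobalFitResult(tau=taus, das=das, offset=off, rms_residual=rms,
                           n_iter=int(best.nfev))


def fit_single_trace(
    times: np.ndarray,
    values: np.ndarray,
    n_exp: int,
    tau_init: np.ndarray | None = None,
    offset: bool = True,
) -> GlobalFitResult:
    """Multi-exponential fit of one kinetic trace (1-row specialisation of
    :func:`global_exp_fit`)."""
    A = SpectraMatrix(wavelengths=np.array([0.0]), times=np.asarray(times, dtype=float),
                      dA=np.atleast_2d(np.asarray(values, dtype=float)))
    return global_exp_fit(A, n_exp, tau_init=tau_init, offset=offset)


# --------------------------------------------------------------------------
# CSV I/O: first row = times (s), first column = wavelengths (nm)
# --------------------------------------------------------------------------

def write_spectra_csv(A: SpectraMatrix, path: str) -> None:
    df = pd.DataFrame(A.dA, index=A.wavelengths, columns=A.times)
    df.index.name = "wavelength_nm"
    df.to_csv(path)


def read_spectra_csv(path: str) -> SpectraMatrix:
    df = pd.read_csv(path, index_col=0)
    return SpectraMatrix(
        wavelengths=df.index.to_numpy(dtype=float),
        times=np.array([float(c) for c in df.columns]),
        dA=df.to_numpy(dtype=float),
    )
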