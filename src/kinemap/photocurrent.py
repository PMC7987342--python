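"""Laser-flash photocurrent processing.

Whole-cell patch-clamp traces triggered by a nanosecond laser flash are
processed in the order: baseline correction and trigger alignment ->
logarithmic binning (default 50 bins per temporal decade) -> normalisation to
the peak photocurrent of the -60 mV reference trace of the same cell ->
averaging over repetitions.  Passive (voltage-driven) photocurrents are
isolated by subtracting the 0 mV trace, which carries only the intra-protein
charge-transfer component; the late passive current decays biexponentially.

Binning uses the arithmetic mean within log-uniform bins; empty bins are
dropped (and counted), not interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .kinetics_spectra import fit_single_trace

__all__ = [
    "CurrentTrace",
    "BinnedTrace",
    "BiexpFit",
    "baseline_and_align",
    "log_bin",
    "normalize_to_peak",
    "passive_current",
    "fit_decay_biexponential",
]


@dataclass
class CurrentTrace:
    """One photocurrent recording: time (s, relative to the laser trigger),
    current (pA), and the recording conditions."""

    t: np.ndarray
    I: np.ndarray
    voltage: float            # mV
    pH: float = 7.2
    cell_id: str = "cell1"
    repetition: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.shape != self.I.shape:
            raise ValueError("t and I must have the same length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")


@dataclass
class BinnedTrace:
    """Log-binned trace: geometric bin centers (s) and per-bin mean currents."""

    centers: np.ndarray
    means: np.ndarray
    bins_per_decade: int
    n_points: np.ndarray
    n_empty_dropped: int = 0
    voltage: float = 0.0
    cell_id: str = ""


@dataclass(frozen=True)
class BiexpFit:
    """A_f exp(-t/tau_f) + A_s exp(-t/tau_s) with tau_fast < tau_slow."""

    tau_fast: float
    tau_slow: float
    amp_fast: float
    amp_slow: float
    degenerate: bool = False

    @property
    def amplitude_ratio(self) -> float:
        """|A_fast| / |A_slow|."""
        return abs(self.amp_fast) / abs(self.amp_slow) if self.amp_slow else np.inf


def baseline_and_align(
    trace: CurrentTrace,
    trigger_time: float,
    baseline_window: tuple[float, float],
) -> CurrentTrace:
    """Subtract the mean current of ``baseline_window`` (which must precede the
    trigger) and shift times so the trigger sits at t = 0."""
    lo, hi = baseline_window
    if hi > trigger_time:
        raise ValueError("baseline window must precede the trigger")
    mask = (trace.t >= lo) & (trace.t <= hi)
    if not np.any(mask):
        raise ValueError("baseline window contains no samples")
    base = float(trace.I[mask].mean())
    return replace(trace, t=trace.t - trigger_time, I=trace.I - base)


def log_bin(
    trace: CurrentTrace,
    bins_per_decade: int = 50,
    t_start: float | None = None,
) -> BinnedTrace:
    """Bin a trace to log-uniform time bins (default 50 per decade).

    ``t_start`` defaults to the first positive sample time (a log axis needs
    t > 0).  Bin value = arithmetic mean of the samples in the bin; empty bins
    are dropped with their count recorded.
    """
    if t_start is None:
        pos = trace.t[trace.t > 0]
        if pos.size == 0:
            raise ValueError("trace has no positive times")
        t_start = float(pos[0])
    if t_start <= 0:
        raise ValueError("t_start must be > 0 for logarithmic binning")
    t_max = float(trace.t[-1])
    if t_max <= t_start:
        raise ValueError("trace must extend beyond t_start")
    n_bins = int(np.ceil((np.log10(t_max) - np.log10(t_start)) * bins_per_decade - 1e-9))
    edges = t_start * 10 ** (np.arange(n_bins + 1) / bins_per_decade)
    mask = (trace.t >= t_start) & (trace.t <= edges[-1])
    t, y = trace.t[mask], trace.I[mask]
    which = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=y, minlength=n_bins)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = counts > 0
    return BinnedTrace(
        centers=centers[keep],
        means=sums[keep] / counts[keep],
        bins_per_decade=bins_per_decade,
        n_points=counts[keep],
        n_empty_dropped=int(np.count_nonzero(~keep)),
        voltage=trace.voltage,
        cell_id=trace.cell_id,
    )


def normalize_to_peak(
    traces: list[CurrentTrace],
    reference_voltage: float = -60.0,
) -> list[CurrentTrace]:
    """Normalise every trace of a cell by the absolute peak current of that
    cell's reference-voltage trace (default -60 mV)."""
    out: list[CurrentTrace] = []
    cells = {tr.cell_id for tr in traces}
    for cell in cells:
        group = [tr for tr in traces if tr.cell_id == cell]
        refs = [tr for tr in group if np.isclose(tr.voltage, reference_voltage)]
        if not refs:
            raise ValueError(
                f"cell {cell!r} has no trace at the reference voltage {reference_voltage} mV"
            )
        peak = max(float(np.max(np.abs(tr.I))) for tr in refs)
        if peak == 0:
            raise ValueError(f"reference trace of cell {cell!r} is identically zero")
        out.extend(replace(tr, I=tr.I / peak) for tr in group)
    return out


def passive_current(trace_at_V: CurrentTrace, trace_at_0mV: CurrentTrace) -> CurrentTrace:
    """Passive photocurrent I_V - I_0mV.

    The 0 mV trace contains only the voltage-independent charge-transfer
    component, so the pointwise difference isolates the voltage-driven
    current.  If the time axes differ, both traces are linearly resampled on
    the coarser axis restricted to the overlap.
    """
    a, b = trace_at_V, trace_at_0mV
    if a.t[0] > b.t[-1] or b.t[0] > a.t[-1]:
        raise ValueError("traces do not overlap in time")
    if len(a.t) == len(b.t) and np.allclose(a.t, b.t):
        t, Ia, Ib = a.t, a.I, b.I
    else:
        lo, hi = max(a.t[0], b.t[0]), min(a.t[-1], b.t[-1])
        coarse = a.t if len(a.t) <= len(b.t) else b.t
        t = coarse[(coarse >= lo) & (coarse <= hi)]
        if t.size == 0:
            raise ValueError("no common time samples after resampling")
        Ia = np.interp(t, a.t, a.I)
        Ib = np.interp(t, b.t, b.I)
    return CurrentTrace(
        t=t, I=Ia - Ib, voltage=a.voltage, pH=a.pH, cell_id=a.cell_id,
        repetition=a.repetition,
    )


def fit_decay_biexponential(
    trace: CurrentTrace,
    fit_window: tuple[float, float],
) -> BiexpFit:
    """Fit A_f exp(-t/tau_f) + A_s exp(-t/tau_s) to the decay phase.

    ``fit_window`` selects the decaying section (>= 6 samples).  If the two
    time constants come out nearly equal or one amplitude is negligible the
    fit is flagged ``degenerate`` (the decay is effectively
    single-exponential).
    """
    lo, hi = fit_window
    mask = (trace.t >= lo) & (trace.t <= hi)
    if np.count_nonzero(mask) < 6:
        raise ValueError("fit window must contain at least 6 samples")
    t = trace.t[mask] - lo        # fit relative to window start for conditioning
    y = trace.I[mask]
    res = fit_single_trace(t, y, n_exp=2, offset=False)
    (tf, ts), (af, as_) = res.tau, res.das[:, 0]
    degenerate = bool(
        ts / tf < 1.2 or min(abs(af), abs(as_)) < 1e-3 * max(abs(af), abs(as_), 1e-300)
    )
    if degenerate:
        warnings.warn("biexponential fit is degenerate (effectively single-exponential)",
                      stacklevel=2)
    return BiexpFit(tau_fast=float(tf), tau_slow=float(ts),
                    amp_fast=float(af), amp_slow=float(as_), degenerate=degenerate)
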