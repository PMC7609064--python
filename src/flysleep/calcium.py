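"""Photobleaching-corrected dF/F0 quantification of fluorescence traces.

A genetically encoded calcium indicator (e.g. GCaMP) is imaged at 5-s
intervals for 5 min while ATP is perfused for 1 min after a 1-min baseline.
Continuous imaging bleaches the fluorophore, so the raw trace rides on a
slow exponential decay.  The correction fits F(t) = A*exp(-k*t) + C to two
transient-free windows — 30-60 s before ATP onset and 150-180 s after ATP
offset — and subtracts the decaying component A*exp(-k*t) from the raw
trace.  Only the decaying term is removed: subtracting the full fitted
curve would drive the baseline toward zero and make the subsequent F0
normalization unstable (a ``full_subtraction`` switch implements the
literal alternative).  F0 is the mean detrended intensity over the 30 s
before ATP onset; dF/F0 = (F - F0)/F0, and the reported peak response is
the maximum of a short moving average of dF/F0 over the perfusion window
plus 60 s of washout (the smoothing suppresses single-frame noise that
would otherwise bias a pointwise maximum upward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PerfusionProtocol",
    "FluorescenceTrace",
    "BleachFit",
    "fit_bleach",
    "detrend",
    "compute_f0",
    "normalize_and_peak",
    "process_trace",
    "PEAK_SMOOTH_FRAMES",
]

PEAK_SMOOTH_FRAMES = 5  # 25 s boxcar at 5-s sampling


@dataclass(frozen=True)
class PerfusionProtocol:
    """Timing of the imaging run: baseline, ATP pulse, total duration (s)."""

    sample_interval_s: float = 5.0
    baseline_duration_s: float = 60.0
    atp_start_s: float = 60.0
    atp_end_s: float = 120.0
    total_duration_s: float = 300.0

    def __post_init__(self) -> None:
        if not 0 < self.atp_start_s < self.atp_end_s <= self.total_duration_s:
            raise ValueError("need 0 < atp_start < atp_end <= total duration")
        if self.atp_start_s != self.baseline_duration_s:
            raise ValueError("ATP starts at the end of the baseline period")

    @property
    def fit_windows(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """The two transient-free windows used for the bleach fit:
        [atp_start-30, atp_start) and [atp_end+150, atp_end+180)."""
        return (
            (self.atp_start_s - 30.0, self.atp_start_s),
            (self.atp_end_s + 150.0, self.atp_end_s + 180.0),
        )


@dataclass
class FluorescenceTrace:
    """Sampled ROI intensities; detrended/dFF filled by the pipeline."""

    times_s: np.ndarray
    raw_F: np.ndarray
    detrended_F: np.ndarray | None = None
    dFF: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.raw_F = np.asarray(self.raw_F, dtype=float)
        if self.times_s.shape != self.raw_F.shape:
            raise ValueError("times and intensities must have equal length")
        if len(self.times_s) > 1 and not (np.diff(self.times_s) > 0).all():
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class BleachFit:
    """Exponential photobleach model F(t) = A*exp(-k*t) + C."""

    amplitude_A: float
    rate_k: float
    offset_C: float
    fit_window_times: tuple[tuple[float, float], tuple[float, float]]

    def decay(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude_A * np.exp(-self.rate_k * np.asarray(t, dtype=float))

    def curve(self, t: np.ndarray) -> np.ndarray:
        return self.decay(t) + self.offset_C


def _window_mask(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (t >= lo) & (t < hi)  # half-open: sample in iff timestamp inside


def fit_bleach(
    trace: FluorescenceTrace, protocol: PerfusionProtocol
) -> BleachFit:
    """Least-squares exponential-decay fit on the two transient-free windows.

    Initialized from the window means (amplitude = level drop, offset =
    late-window level).  If the optimizer does not converge, a log-linear
    fit of log(F - C0) is used with a warning.  Note the two short windows
    identify the amplitude/offset split only weakly when the decay is
    slow relative to the trace (see the methods documentation): the
    detrended curve is reliable, but the absolute offset — and hence the
    dF/F0 scale — carries substantial uncertainty in that regime.
    """
    t = trace.times_s
    (w1, w2) = protocol.fit_windows
    m1 = _window_mask(t, *w1)
    m2 = _window_mask(t, *w2)
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("bleach-fit window lies outside the trace")
    mask = m1 | m2
    tf, ff = t[mask], trace.raw_F[mask]

    if np.ptp(ff) == 0:
        return BleachFit(0.0, 0.0, float(ff.mean()), protocol.fit_windows)

    f1, f2 = float(trace.raw_F[m1].mean()), float(trace.raw_F[m2].mean())
    p0 = (
        max(f1 - f2, 1e-6 * abs(f1) + 1e-12),
        1.0 / protocol.total_duration_s,
        f2,
    )
    try:
        popt, _ = curve_fit(
            lambda x, A, k, C: A * np.exp(-k * x) + C,
            tf,
            ff,
            p0=p0,
            bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        A, k, C = (float(v) for v in popt)
    except RuntimeError:
        warnings.warn("bleach fit did not converge; using log-linear fallback")
        C0 = min(f1, f2) - 0.05 * abs(np.ptp(ff))
        y = np.log(np.maximum(ff - C0, 1e-12))
        slope, intercept = np.polyfit(tf, y, 1)
        A, k, C = float(np.exp(intercept)), float(max(-slope, 0.0)), float(C0)
    return BleachFit(A, k, C, protocol.fit_windows)


def detrend(
    trace: FluorescenceTrace,
    fit: BleachFit,
    full_subtraction: bool = False,
) -> FluorescenceTrace:
    """Remove the fitted bleach from the raw trace.

    Default removes only the decaying component A*exp(-k*t), preserving the
    offset C so that F0 stays on the intensity scale; ``full_subtraction``
    subtracts the entire fitted curve (the literal reading).
    """
    corrected = trace.raw_F - fit.decay(trace.times_s)
    if full_subtraction:
        corrected = corrected - fit.offset_C
    return FluorescenceTrace(
        times_s=trace.times_s, raw_F=trace.raw_F, detrended_F=corrected
    )


def compute_f0(trace: FluorescenceTrace, protocol: PerfusionProtocol) -> float:
    """Baseline F0: mean detrended intensity over the 30 s before ATP onset."""
    if trace.detrended_F is None:
        raise ValueError("trace has not been detrended")
    m = _window_mask(
        trace.times_s, protocol.atp_start_s - 30.0, protocol.atp_start_s
    )
    if not m.any():
        raise ValueError("F0 window lies outside the trace")
    f0 = float(trace.detrended_F[m].mean())
    if f0 <= 0:
        raise ValueError(
            "F0 <= 0: normalization undefined; check the detrend mode "
            "(full_subtraction removes the baseline offset)"
        )
    return f0


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    return np.convolve(x, np.ones(w) / w, mode="valid")


def normalize_and_peak(
    trace: FluorescenceTrace,
    f0: float,
    protocol: PerfusionProtocol,
    peak_window: tuple[float, float] | None = None,
    smooth_frames: int = PEAK_SMOOTH_FRAMES,
) -> tuple[np.ndarray, float]:
    """dF/F0 series and the peak response.

    dFF(t) = (detrended F(t) - F0)/F0.  The peak is the maximum of a
    ``smooth_frames``-frame moving average of dFF over ``peak_window``
    (default [atp_start, atp_end + 60 s], covering perfusion and early
    washout).
    """
    if trace.detrended_F is None:
        raise ValueError("trace has not been detrended")
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    dff = (trace.detrended_F - f0) / f0
    trace.dFF = dff
    if peak_window is None:
        peak_window = (protocol.atp_start_s, protocol.atp_end_s + 60.0)
    m = _window_mask(trace.times_s, peak_window[0], peak_window[1] + 1e-9)
    seg = dff[m]
    if len(seg) == 0:
        raise ValueError("peak window contains no samples")
    w = min(smooth_frames, len(seg))
    peak = float(_moving_average(seg, w).max())
    return dff, peak


def process_trace(
    trace: FluorescenceTrace,
    protocol: PerfusionProtocol,
    full_subtraction: bool = False,
    peak_window: tuple[float, float] | None = None,
    smooth_frames: int = PEAK_SMOOTH_FRAMES,
) -> tuple[FluorescenceTrace, BleachFit, float, float]:
    """Full pipeline: fit bleach, detrend, F0, dF/F0 and peak.

    Returns (processed trace, bleach fit, F0, peak response).
    """
    fit = fit_bleach(trace, protocol)
    corrected = detrend(trace, fit, full_subtraction=full_subtraction)
    f0 = compute_f0(corrected, protocol)
    _, peak = normalize_and_peak(
        corrected, f0, protocol, peak_window=peak_window, smooth_frames=smooth_frames
    )
    return corrected, fit, f0, peak
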