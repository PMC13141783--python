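"""Robust signal-processing primitives shared by the glucose and photometry streams.

All series live on a uniform 1 Hz grid whose time axis is expressed in
seconds relative to the oral gavage (t = 0 at gavage).  The primitives here
are deliberately simple and robust: median/MAD-based despiking, centered
median filtering, strictly causal moving averages, baseline subtraction and
z-scoring over the pre-gavage window, a zero-phase Butterworth low-pass, and
least-squares removal of a reference (isosbestic) channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "UniformTrace",
    "RobustScale",
    "robust_scale",
    "despike_mad",
    "median_filter_centered",
    "causal_moving_average",
    "finite_difference_derivative",
    "baseline_subtract",
    "zscore_baseline",
    "lowpass_zero_phase",
    "regress_out_reference",
]

#: multiplier converting a median absolute deviation into a robust SD estimate
MAD_SCALE = 1.4826


@dataclass
class UniformTrace:
    """A uniformly sampled scalar series.

    Parameters
    ----------
    values
        Real-valued samples.
    t0
        Time of the first sample in seconds relative to the gavage (t = 0 at
        gavage; negative values are pre-gavage baseline).
    fs
        Sampling rate in Hz.  Acquisition in this pipeline is fixed at 1 Hz.
    """

    values: np.ndarray
    t0: float = 0.0
    fs: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("UniformTrace values must be one-dimensional")
        if self.values.size < 2:
            raise ValueError("UniformTrace requires length >= 2")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    # -- time axis ---------------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def t(self) -> np.ndarray:
        """Time axis in seconds (strictly increasing)."""
        return self.t0 + np.arange(self.n) / self.fs

    def with_values(self, values: np.ndarray) -> "UniformTrace":
        """A new trace on the same time axis with different samples."""
        return UniformTrace(np.asarray(values, dtype=float), t0=self.t0, fs=self.fs)

    # -- windowing ---------------------------------------------------------
    def window_mask(self, t_start: float, t_stop: float) -> np.ndarray:
        """Boolean mask of samples with t_start <= t < t_stop (seconds)."""
        t = self.t
        return (t >= t_start) & (t < t_stop)

    def window_values(self, t_start: float, t_stop: float) -> np.ndarray:
        vals = self.values[self.window_mask(t_start, t_stop)]
        if vals.size == 0:
            raise ValueError(
                f"window [{t_start}, {t_stop}) s does not overlap trace "
                f"spanning [{self.t0}, {self.t[-1]}] s"
            )
        return vals

    def index_of_time(self, time_s: float) -> int:
        """Nearest sample index for a time in seconds (clipped to range)."""
        idx = int(round((time_s - self.t0) * self.fs))
        return int(np.clip(idx, 0, self.n - 1))


@dataclass(frozen=True)
class RobustScale:
    """Median and MAD-based robust scale (1.4826 x MAD) of a sample."""

    center: float
    scale: float


def robust_scale(x: np.ndarray) -> RobustScale:
    """Robust center/scale: median and 1.4826 x median absolute deviation."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute robust scale of an empty sample")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return RobustScale(center=med, scale=MAD_SCALE * mad)


# ---------------------------------------------------------------------------
# despiking
# ---------------------------------------------------------------------------

def despike_flags(values: np.ndarray, k: float) -> np.ndarray:
    """Boolean flags for the MAD despiking rule |y - median| > k * MAD.

    When MAD = 0 (at least half the samples equal the median) the threshold
    is effectively infinite; only samples departing from the median by more
    than a tiny absolute guard are flagged, so constant traces pass through
    untouched.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad > 0:
        return np.abs(values - med) > k * mad
    guard = 1e-9 * abs(med) + 1e-12
    return np.abs(values - med) > guard


def despike_mad(
    trace: UniformTrace,
    k: float,
    label: str = "trace",
    detrend_window: int | None = None,
) -> UniformTrace:
    """Replace MAD-rule outliers by linear interpolation between neighbours.

    Samples with ``|y - median| > k * MAD`` are replaced by linear
    interpolation between the nearest unflagged neighbours; flagged samples
    at the boundaries take the nearest unflagged value.  All other samples
    are returned bit-identical.

    With ``detrend_window`` set (odd number of samples), the rule is applied
    to the residual from a centered rolling median of that window instead of
    to the raw values.  Impulsive spikes survive the detrending and are
    flagged, while slow physiological structure (a glucose excursion, a
    sustained neural inhibition) stays below threshold — a session-scale
    trace should always be despiked this way, since its slow excursion would
    otherwise dominate the global deviation statistics.
    """
    if k <= 0:
        raise ValueError("despike threshold k must be positive")
    values = trace.values
    if np.isnan(values).any():
        raise ValueError(f"{label}: despiking requires a NaN-free input")
    if detrend_window is not None:
        slow = median_filter_centered(trace, detrend_window).values
        flags = despike_flags(values - slow, k)
    else:
        flags = despike_flags(values, k)
    if not flags.any():
        return trace.with_values(values.copy())
    if flags.all():
        raise ValueError(f"{label}: every sample flagged by the MAD rule")
    idx = np.arange(values.size)
    good = ~flags
    out = values.copy()
    # np.interp holds edge values constant outside the support, which
    # implements the nearest-unflagged boundary policy.
    out[flags] = np.interp(idx[flags], idx[good], values[good])
    return trace.with_values(out)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def median_filter_centered(trace: UniformTrace, window: int) -> UniformTrace:
    """Centered sliding-median filter with shrunken windows at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("median filter window must be odd and >= 1")
    if window > trace.n:
        raise ValueError(
            f"median filter window ({window}) larger than trace ({trace.n})"
        )
    values = trace.values
    if window == 1:
        return trace.with_values(values.copy())
    half = window // 2
    out = np.empty_like(values)
    interior = np.lib.stride_tricks.sliding_window_view(values, window)
    out[half: values.size - half] = np.median(interior, axis=1)
    for i in range(half):
        # shrunken centered window kept fully inside the trace
        out[i] = np.median(values[: i + half + 1])
        j = values.size - 1 - i
        out[j] = np.median(values[j - half:])
    return trace.with_values(out)


def causal_moving_average(trace: UniformTrace, window: int) -> UniformTrace:
    """Strictly causal moving mean: out[i] = mean(in[max(0, i-window+1) .. i])."""
    if window < 1:
        raise ValueError("moving-average window must be >= 1")
    values = trace.values
    csum = np.cumsum(values)
    out = np.empty_like(values)
    n = values.size
    w = min(window, n)
    # warm-up region uses the partial (growing) window
    out[:w] = csum[:w] / np.arange(1, w + 1)
    if n > w:
        out[w:] = (csum[w:] - csum[:-w]) / w
    return trace.with_values(out)


def finite_difference_derivative(trace: UniformTrace, smooth_window: int) -> UniformTrace:
    """First differences at the sample spacing, causally smoothed.

    Output units are (input units) per second.  The leading sample is padded
    with 0 so the output shares the input's time axis.
    """
    values = trace.values
    diff = np.empty_like(values)
    diff[0] = 0.0
    diff[1:] = np.diff(values) * trace.fs
    deriv = trace.with_values(diff)
    if smooth_window > 1:
        deriv = causal_moving_average(deriv, smooth_window)
    return deriv


# ---------------------------------------------------------------------------
# baseline normalisation
# ---------------------------------------------------------------------------

def baseline_subtract(
    trace: UniformTrace, baseline_window: tuple[float, float]
) -> tuple[UniformTrace, float]:
    """Subtract the median over the baseline window; also return that median."""
    base = float(np.median(trace.window_values(*baseline_window)))
    return trace.with_values(trace.values - base), base


def zscore_baseline(
    trace: UniformTrace,
    baseline_window: tuple[float, float],
    label: str = "trace",
) -> UniformTrace:
    """Center and scale by the baseline-window mean and SD."""
    base = trace.window_values(*baseline_window)
    mu = float(np.mean(base))
    sd = float(np.std(base, ddof=0))
    if sd <= 0:
        raise ValueError(f"{label}: zero baseline SD, cannot z-score")
    return trace.with_values((trace.values - mu) / sd)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def lowpass_zero_phase(
    trace: UniformTrace, cutoff_period_min: float, order: int = 3
) -> UniformTrace:
    """Zero-phase (forward-backward) Butterworth low-pass defined by period.

    ``cutoff_period_min`` is the cutoff expressed as a period in minutes; the
    corresponding cutoff frequency is 1 / (60 * cutoff_period_min) Hz.  Two
    passes square the single-pass magnitude response and cancel the phase.
    """
    if order < 1:
        raise ValueError("filter order must be >= 1")
    cutoff_hz = 1.0 / (60.0 * cutoff_period_min)
    nyq = trace.fs / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError("cutoff period must map inside (0, Nyquist)")
    sos = _sig.butter(order, cutoff_hz, btype="low", fs=trace.fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if trace.n <= padlen:
        raise ValueError(
            f"trace of {trace.n} samples too short for zero-phase filtering "
            f"(needs > {padlen})"
        )
    return trace.with_values(_sig.sosfiltfilt(sos, trace.values))


# ---------------------------------------------------------------------------
# reference-channel regression
# ---------------------------------------------------------------------------

def regress_out_reference(
    signal: UniformTrace,
    reference: UniformTrace,
    fit_window: tuple[float, float] | None = None,
) -> UniformTrace:
    """Remove the least-squares projection of the reference from the signal.

    Fits ``signal ~ a * reference + b`` by ordinary least squares and returns
    the residual ``signal - (a * reference + b)`` over the full trace.  A
    constant reference degenerates to intercept-only removal (mean
    subtraction).

    With ``fit_window`` set, the coefficients are estimated only on that
    time window (seconds) and then applied to the whole trace.  Fitting on a
    pre-event window where the signal is at baseline keeps slow *neural*
    components out of the fitted coefficient: a global fit would otherwise
    partially absorb any sustained response that happens to covary with the
    drift over the session.
    """
    if signal.n != reference.n or signal.t0 != reference.t0:
        raise ValueError("signal and reference must share the same time axis")
    y = signal.values
    x = reference.values
    if fit_window is None:
        mask = np.ones(signal.n, dtype=bool)
    else:
        mask = signal.window_mask(*fit_window)
        if mask.sum() < 3:
            raise ValueError("fit window contains fewer than 3 samples")
    if np.ptp(x[mask]) == 0:
        return signal.with_values(y - np.mean(y[mask]))
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design[mask], y[mask], rcond=None)
    return signal.with_values(y - design @ coef)
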