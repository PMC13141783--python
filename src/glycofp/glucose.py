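"""Cleaning of continuous arterial glucose traces and glycemic-excursion metrics.

The continuous glucose monitor samples arterial glucose (mg/dL) at 1 Hz.
Two documented processing branches are maintained:

* **metrics branch** — despike (MAD, k = 2) -> centered median filter
  (7 samples) -> causal moving average (60 s) -> subtraction of the median
  over the pre-gavage baseline (-25..0 min), yielding the excursion
  ``delta_g``; its derivative is the finite difference of the 2-min
  causally-boxcar-smoothed excursion, causally smoothed over 60 s.
* **onset branch** — the level ``y0(t)`` is the despiked, median-filtered
  trace minus the median over the last 5 pre-gavage minutes; its derivative
  is the finite difference of the 2-min causally-boxcar-smoothed ``y0``,
  smoothed over 60 s.  Onset thresholds are robust (median/MAD) statistics
  of the level and derivative over the pre-gavage segment only.

Onset is declared at the first post-gavage sample beginning a sustained
(>= 1 min) run in which either the derivative clears the slope threshold or
the level clears the level threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .signal_core import (
    UniformTrace,
    baseline_subtract,
    causal_moving_average,
    despike_mad,
    finite_difference_derivative,
    median_filter_centered,
    robust_scale,
)

__all__ = [
    "GlucoseTrace",
    "OnsetThresholds",
    "GlucoseMetrics",
    "preprocess_glucose",
    "compute_onset_thresholds",
    "detect_bg_onset",
    "excursion_summary",
    "iauc_positive",
]

BASELINE_WINDOW_S = (-25.0 * 60.0, 0.0)
ONSET_BASELINE_WINDOW_S = (-5.0 * 60.0, 0.0)
PEAK_WINDOW_S = (0.0, 90.0 * 60.0)
PEAK_DERIV_WINDOW_S = (0.0, 30.0 * 60.0)


@dataclass
class GlucoseTrace:
    """A cleaned glucose session with both processing branches attached."""

    raw: UniformTrace                 # despiked-but-unsmoothed level, mg/dL
    delta_g: UniformTrace             # baseline-subtracted smoothed level, mg/dL
    derivative: UniformTrace          # metrics-branch derivative, mg/dL per s
    baseline_value: float             # mg/dL, median of -25..0 min
    onset_level: UniformTrace         # onset-branch level y0(t) (unsmoothed), mg/dL
    onset_derivative: UniformTrace    # onset-branch derivative, mg/dL per s
    raw_delta: UniformTrace           # despiked raw minus baseline (half-max series)


@dataclass(frozen=True)
class OnsetThresholds:
    """Robust baseline-derived thresholds for glucose-rise onset detection."""

    m_d: float        # median of pre-gavage onset-branch derivative
    sigma_d: float    # 1.4826 * MAD of pre-gavage derivative
    sigma_y: float    # 1.4826 * MAD of pre-gavage onset-branch level
    z: float          # multiplier (3 by default)

    @property
    def t_slope(self) -> float:
        return self.m_d + self.z * self.sigma_d

    @property
    def t_level(self) -> float:
        return 3.0 * self.sigma_y


@dataclass
class GlucoseMetrics:
    """Per-session glycemic-excursion summary.

    Times are in seconds relative to the gavage; amplitudes in mg/dL; the
    derivative in mg/dL per second; iAUC in mg/dL * min.  Optional fields
    are ``None`` when the corresponding event was not detected.
    """

    onset_time_s: Optional[float]
    peak_delta_g: float
    peak_time_s: float
    peak_derivative: float
    peak_derivative_time_s: float
    half_max_return_time_s: Optional[float]
    plateau_interval_s: Optional[tuple[float, float]]
    return_to_baseline_time_s: Optional[float]
    iauc_mg_dl_min: float
    baseline_value: float


def preprocess_glucose(
    raw: UniformTrace,
    despike_k: float = 2.0,
    median_window: int = 7,
    smooth_window: int = 60,
    boxcar_window: int = 120,
    despike_detrend_window: int = 31,
    baseline_window_s: tuple[float, float] = BASELINE_WINDOW_S,
    onset_baseline_window_s: tuple[float, float] = ONSET_BASELINE_WINDOW_S,
) -> GlucoseTrace:
    """Run both glucose cleaning branches on a raw 1 Hz mg/dL trace."""
    if raw.t0 > baseline_window_s[0] or raw.t[-1] < PEAK_WINDOW_S[1] - 1:
        raise ValueError(
            "glucose trace must span at least [-25, +90] min around the gavage; "
            f"got [{raw.t0 / 60:.1f}, {raw.t[-1] / 60:.1f}] min"
        )
    despiked = despike_mad(raw, despike_k, label="glucose",
                       detrend_window=despike_detrend_window)
    cleaned = median_filter_centered(despiked, median_window)

    # metrics branch: the derivative of delta_g gets one extra causal
    # smoothing stage, whose group delay (half a sample for the difference
    # plus (w-1)/2 for the moving average, = w/2 at 1 Hz) would otherwise
    # misalign it with the level and photometry streams that share the rest
    # of the chain; its time axis is re-centered by that known constant.
    smoothed = causal_moving_average(cleaned, smooth_window)
    delta_g, baseline_value = baseline_subtract(smoothed, baseline_window_s)
    deriv_raw = finite_difference_derivative(delta_g, smooth_window).values
    shift = smooth_window // 2
    recentered = np.concatenate([
        deriv_raw[shift:], np.full(shift, deriv_raw[-1])
    ])
    derivative = delta_g.with_values(recentered)

    # onset branch: y0 is the cleaned level minus the short (-5..0 min)
    # median baseline; the 2-min causal boxcar exists to stabilize the
    # derivative, while the level condition tests y0 itself (its larger
    # sample-to-sample scale is what keeps the level threshold from firing
    # on slow wander of a smoothed series)
    onset_base = float(np.median(cleaned.window_values(*onset_baseline_window_s)))
    y0 = cleaned.with_values(cleaned.values - onset_base)
    y0_smooth = causal_moving_average(y0, boxcar_window)
    onset_derivative = finite_difference_derivative(y0_smooth, smooth_window)

    raw_delta = despiked.with_values(despiked.values - baseline_value)
    return GlucoseTrace(
        raw=despiked,
        delta_g=delta_g,
        derivative=derivative,
        baseline_value=baseline_value,
        onset_level=y0,
        onset_derivative=onset_derivative,
        raw_delta=raw_delta,
    )


def compute_onset_thresholds(g: GlucoseTrace, z: float = 3.0) -> OnsetThresholds:
    """Robust thresholds from the pre-gavage (t < 0) onset-branch segment."""
    pre = g.onset_level.t < 0
    if not pre.any():
        raise ValueError("no pre-gavage samples available for thresholds")
    d_pre = robust_scale(g.onset_derivative.values[pre])
    y_pre = robust_scale(g.onset_level.values[pre])
    return OnsetThresholds(m_d=d_pre.center, sigma_d=d_pre.scale,
                           sigma_y=y_pre.scale, z=z)


def detect_bg_onset(
    g: GlucoseTrace,
    thresholds: OnsetThresholds,
    sustain_s: int = 60,
) -> Optional[float]:
    """First sustained post-gavage glucose rise, or ``None`` if undetected.

    A sample provides evidence when its onset-branch derivative exceeds the
    slope threshold OR its onset-branch level exceeds the level threshold;
    onset is the first t >= 0 sample beginning a run of at least
    ``sustain_s`` consecutive evidence samples.
    """
    if sustain_s < 1:
        raise ValueError("sustain must be >= 1 sample")
    t = g.onset_level.t
    post = t >= 0
    cond = (g.onset_derivative.values > thresholds.t_slope) | (
        g.onset_level.values > thresholds.t_level
    )
    cond = cond & post
    # length of the run of consecutive True values starting at each index
    run = np.zeros(cond.size, dtype=int)
    acc = 0
    for i in range(cond.size - 1, -1, -1):
        acc = acc + 1 if cond[i] else 0
        run[i] = acc
    hits = np.flatnonzero((run >= sustain_s) & post)
    if hits.size == 0:
        return None
    return float(t[hits[0]])


def iauc_positive(
    g: GlucoseTrace, window_s: tuple[float, float] = PEAK_WINDOW_S
) -> float:
    """Positive-only incremental area under delta_g over the window, mg/dL*min."""
    mask = g.delta_g.window_mask(*window_s)
    if not mask.any():
        raise ValueError("iAUC window does not overlap the trace")
    vals = np.maximum(g.delta_g.values[mask], 0.0)
    t_min = g.delta_g.t[mask] / 60.0
    return float(np.trapezoid(vals, t_min))


def _first_sustained(
    mask: np.ndarray, start_idx: int, sustain: int
) -> Optional[int]:
    """Index of the first run of >= sustain True samples at or after start_idx."""
    run = 0
    for i in range(start_idx, mask.size):
        run = run + 1 if mask[i] else 0
        if run >= sustain:
            return i - sustain + 1
    return None


def excursion_summary(
    g: GlucoseTrace,
    onset_time_s: Optional[float],
    plateau_band_frac: float = 0.1,
    plateau_sustain_s: int = 120,
) -> GlucoseMetrics:
    """All glycemic-excursion metrics for one cleaned session.

    Peak excursion is located on the smoothed ``delta_g`` within 0-90 min and
    the peak derivative within 0-30 min.  Half-max recovery is the first
    post-peak crossing of half the peak, linearly interpolated on the
    despiked-but-unsmoothed baseline-subtracted series.  The plateau is the
    first post-peak-derivative interval where the smoothed derivative stays
    within ``plateau_band_frac`` of the peak rise derivative for at least
    ``plateau_sustain_s``; return to baseline is the earlier of the first
    non-positive excursion after the peak and the first sustained relaxation
    of the derivative above the matching negative band.
    """
    dg = g.delta_g
    t = dg.t
    peak_mask = dg.window_mask(*PEAK_WINDOW_S)
    peak_idx_local = int(np.argmax(dg.values[peak_mask]))
    peak_idx = np.flatnonzero(peak_mask)[peak_idx_local]
    peak_delta_g = float(dg.values[peak_idx])
    peak_time = float(t[peak_idx])

    deriv_mask = g.derivative.window_mask(*PEAK_DERIV_WINDOW_S)
    d_idx_local = int(np.argmax(g.derivative.values[deriv_mask]))
    d_idx = np.flatnonzero(deriv_mask)[d_idx_local]
    peak_derivative = float(g.derivative.values[d_idx])
    peak_derivative_time = float(t[d_idx])

    half_max_return = _half_max_return(g, peak_idx, peak_delta_g)

    band = plateau_band_frac * max(peak_derivative, 0.0)
    deriv = g.derivative.values
    plateau_start = _first_sustained(np.abs(deriv) <= band, d_idx + 1,
                                     plateau_sustain_s)
    plateau_interval: Optional[tuple[float, float]] = None
    if plateau_start is not None:
        j = plateau_start
        while j < deriv.size and abs(deriv[j]) <= band:
            j += 1
        plateau_interval = (float(t[plateau_start]), float(t[j - 1]))

    return_time = _return_to_baseline(
        g, peak_idx, band, plateau_sustain_s
    )

    return GlucoseMetrics(
        onset_time_s=onset_time_s,
        peak_delta_g=peak_delta_g,
        peak_time_s=peak_time,
        peak_derivative=peak_derivative,
        peak_derivative_time_s=peak_derivative_time,
        half_max_return_time_s=half_max_return,
        plateau_interval_s=plateau_interval,
        return_to_baseline_time_s=return_time,
        iauc_mg_dl_min=iauc_positive(g),
        baseline_value=g.baseline_value,
    )


def _half_max_return(
    g: GlucoseTrace, peak_idx: int, peak_delta_g: float
) -> Optional[float]:
    """First post-peak crossing of baseline + 0.5*peak on the raw series."""
    level = 0.5 * peak_delta_g
    y = g.raw_delta.values
    t = g.raw_delta.t
    for i in range(peak_idx + 1, y.size):
        if y[i] <= level:
            y0, y1 = y[i - 1], y[i]
            if y1 == y0:
                return float(t[i])
            frac = (y0 - level) / (y0 - y1)
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return None


def _return_to_baseline(
    g: GlucoseTrace, peak_idx: int, band: float, sustain: int
) -> Optional[float]:
    dg = g.delta_g.values
    deriv = g.derivative.values
    t = g.delta_g.t
    amp_idx = None
    for i in range(peak_idx + 1, dg.size):
        if dg[i] <= 0:
            amp_idx = i
            break
    # sustained relaxation: derivative back above -band after the decline began
    decline = np.flatnonzero(deriv[peak_idx:] < -band)
    relax_idx = None
    if decline.size:
        start = peak_idx + int(decline[0])
        relax_idx = _first_sustained(deriv >= -band, start + 1, sustain)
    candidates = [i for i in (amp_idx, relax_idx) if i is not None]
    if not candidates:
        return None
    return float(t[min(candidates)])
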