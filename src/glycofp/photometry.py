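"""Fiber-photometry preprocessing and per-session response metrics.

The activity-dependent channel (465 nm) is first corrected by regressing the
isosbestic reference channel (405 nm) onto it and subtracting the fit, which
removes shared motion and photobleaching components.  The corrected trace is
then despiked, median-filtered, causally smoothed, low-pass filtered with a
zero-phase Butterworth (4-min cutoff period, order 3) and z-scored within
the pre-gavage baseline, yielding ``Z_FP(t)`` with baseline mean 0 and unit
SD.

Response metrics include the early-window peak z deflection, negative and
total AUCs, a spectral onset detector based on band-limited (14-20 min
period) spectrogram power against a jittered pseudo-onset null, and the
aperiodic 1/f^kappa exponent of the baseline power spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as _sig

from .signal_core import (
    UniformTrace,
    causal_moving_average,
    despike_mad,
    lowpass_zero_phase,
    median_filter_centered,
    regress_out_reference,
    zscore_baseline,
)

__all__ = [
    "PhotometryTrace",
    "SpectralOnset",
    "PhotometryMetrics",
    "preprocess_photometry",
    "peak_z_response",
    "negative_auc",
    "total_auc",
    "band_power_onset",
    "psd_aperiodic_slope",
]

BASELINE_WINDOW_S = (-25.0 * 60.0, 0.0)
#: low-frequency band of interest: periods between 14 and 20 minutes,
#: expressed in cycles per minute
SLOW_BAND_CPM = (1.0 / 20.0, 1.0 / 14.0)
#: log-log fit band for the aperiodic PSD exponent (cycles per minute)
PSD_FIT_BAND_CPM = (0.05, 0.5)


@dataclass
class PhotometryTrace:
    """Preprocessed photometry session: corrected signal and baseline z-score."""

    z: UniformTrace          # Z_FP(t), baseline z-units
    corrected: UniformTrace  # reference-regressed signal, arbitrary units


@dataclass
class SpectralOnset:
    """Band-power onset detection result against a jittered pseudo-onset null."""

    bin_times_s: np.ndarray       # spectrogram bin centers, s relative to gavage
    p_real: np.ndarray            # band power per bin
    p_null: np.ndarray            # (n_null, n_bins) null band-power traces
    p_value: np.ndarray           # rank p per bin, in [1/(N+1), 1]
    onset_time_s: Optional[float]  # first significant bin in the detect window
    band_cpm: tuple[float, float]
    n_null: int
    alpha: float


@dataclass
class PhotometryMetrics:
    """Per-session photometry response summary."""

    peak_z_early: float
    peak_z_early_time_s: float
    neg_auc_z_min: Optional[float]   # 0 .. peak-BG time, negative deflections
    total_auc_z_min: float           # 0 .. end of session, unclipped
    psd_slope: float                 # aperiodic exponent kappa
    spectral_onset: Optional[SpectralOnset] = None


def preprocess_photometry(
    signal: UniformTrace,
    reference: UniformTrace,
    despike_k: float = 2.0,
    despike_detrend_window: int = 31,
    median_window: int = 7,
    smooth_window: int = 60,
    lowpass_period_min: float = 4.0,
    lowpass_order: int = 3,
    baseline_window_s: tuple[float, float] = BASELINE_WINDOW_S,
    reference_lowpass_period_min: float = 4.0,
    reference_fit_window_s: tuple[float, float] = (-25.0 * 60.0, -5.0 * 60.0),
    label: str = "session",
) -> PhotometryTrace:
    """Full photometry preprocessing chain, ending in the baseline z-score.

    The reference channel is first low-pass filtered (same cutoff family as
    the signal low-pass) to isolate the slow, non-neural drift it proxies;
    the regression then subtracts that fitted slow component from the
    signal.  Regressing the raw noisy reference instead would attenuate the
    fitted coefficient (errors-in-variables) and leave part of the
    photobleaching drift in the corrected trace.  The coefficients are
    estimated on a pre-event window that ends before anticipatory activity
    can begin, so that the removed component is non-neural by construction;
    a whole-session fit would partially absorb any sustained response that
    covaries with the drift.  Fast shared transients are handled downstream
    by despiking and median filtering.
    """
    drift_proxy = lowpass_zero_phase(reference, reference_lowpass_period_min,
                                     lowpass_order)
    corrected = regress_out_reference(signal, drift_proxy,
                                      fit_window=reference_fit_window_s)
    x = despike_mad(corrected, despike_k, label=label,
                detrend_window=despike_detrend_window)
    x = median_filter_centered(x, median_window)
    x = causal_moving_average(x, smooth_window)
    x = lowpass_zero_phase(x, lowpass_period_min, lowpass_order)
    z = zscore_baseline(x, baseline_window_s, label=label)
    return PhotometryTrace(z=z, corrected=corrected)


def peak_z_response(
    fp: PhotometryTrace,
    window_s: tuple[float, float] = (0.0, 15.0 * 60.0),
    direction: str = "inhibition",
) -> tuple[float, float]:
    """Extremal z deflection in the window and its time.

    ``direction='inhibition'`` returns the minimum (most negative) z;
    ``'excitation'`` the maximum.  Ties resolve to the earliest sample.
    """
    mask = fp.z.window_mask(*window_s)
    if not mask.any():
        raise ValueError("peak window does not overlap the trace")
    vals = fp.z.values[mask]
    times = fp.z.t[mask]
    if direction == "inhibition":
        idx = int(np.argmin(vals))
    elif direction == "excitation":
        idx = int(np.argmax(vals))
    else:
        raise ValueError("direction must be 'inhibition' or 'excitation'")
    return float(vals[idx]), float(times[idx])


def negative_auc(fp: PhotometryTrace, t_end_s: Optional[float]) -> float:
    """Integral of the negative deflections of z from 0 to ``t_end_s``, z*min."""
    if t_end_s is None:
        raise ValueError(
            "no glucose peak time available; use total_auc for this session"
        )
    if t_end_s <= 0:
        raise ValueError("t_end must be after the gavage")
    mask = fp.z.window_mask(0.0, t_end_s)
    vals = np.minimum(fp.z.values[mask], 0.0)
    return float(np.trapezoid(vals, fp.z.t[mask] / 60.0))


def total_auc(fp: PhotometryTrace) -> float:
    """Unclipped integral of z from 0 to the end of the session, z*min."""
    mask = fp.z.t >= 0
    return float(np.trapezoid(fp.z.values[mask], fp.z.t[mask] / 60.0))


def _band_power_series(
    z: UniformTrace,
    band_cpm: tuple[float, float],
    segment_s: float,
    overlap_frac: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Spectrogram band-limited power by time bin (bin times in session s)."""
    nperseg = int(round(segment_s * z.fs))
    noverlap = int(np.floor(nperseg * overlap_frac))
    if z.n < nperseg:
        raise ValueError(
            f"session too short for {segment_s:.0f}-s spectrogram windows"
        )
    freqs, times, sxx = _sig.spectrogram(
        z.values,
        fs=z.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    cpm = freqs * 60.0
    in_band = (cpm >= band_cpm[0]) & (cpm <= band_cpm[1])
    if not in_band.any():
        raise ValueError("no spectrogram frequency bin inside the slow band")
    power = sxx[in_band].mean(axis=0)
    return z.t0 + times, power


def band_power_onset(
    fp: PhotometryTrace,
    band_cpm: tuple[float, float] = SLOW_BAND_CPM,
    n_null: int = 200,
    guard_s: float = 5.0 * 60.0,
    detect_window_s: tuple[float, float] = (-10.0 * 60.0, 10.0 * 60.0),
    alpha: float = 0.05,
    segment_s: float = 20.0 * 60.0,
    overlap_frac: float = 0.99,
    rng: Optional[np.random.Generator] = None,
) -> SpectralOnset:
    """Onset of low-frequency photometry power around the gavage.

    Band-limited spectrogram power is compared, bin by bin, against a null
    built from pseudo-onset alignments of the same session: each pseudo-onset
    re-reads the band-power trace as if the gavage had occurred at that time,
    excluding a guard around the true gavage.  The rank p-value per bin is
    ``(1 + #{null >= real}) / (N + 1)``; the onset is the first bin inside
    the detect window with p < alpha.

    Calibration caveat: the rank-p guarantee P(p <= alpha) <= alpha +
    1/(N+1) assumes the real bin is exchangeable with the pseudo-onset
    nulls, i.e. that the recording holds many independent segments of
    length ``segment_s``.  A 115-min session contains only ~6 independent
    20-min windows, so small-alpha p-values are anti-conservative at that
    length and onset calls should be read descriptively; calibration is
    restored on recordings several hours long.
    """
    if n_null < 20:
        raise ValueError("n_null < 20 gives too coarse a p-value resolution")
    rng = rng if rng is not None else np.random.default_rng()
    bin_t, power = _band_power_series(fp.z, band_cpm, segment_s, overlap_frac)
    hop = bin_t[1] - bin_t[0]

    det_mask = (bin_t >= detect_window_s[0]) & (bin_t <= detect_window_s[1])
    det_idx = np.flatnonzero(det_mask)
    if det_idx.size == 0:
        raise ValueError("detect window contains no spectrogram bins")
    # relative offsets (in bins) of the detect window around an onset
    rel = det_idx - int(np.argmin(np.abs(bin_t)))

    # admissible pseudo-onset bins: full detect window must fit, and the
    # pseudo-onset must sit outside the guard around the true gavage
    all_idx = np.arange(bin_t.size)
    lo, hi = rel.min(), rel.max()
    fits = (all_idx + lo >= 0) & (all_idx + hi < bin_t.size)
    outside_guard = np.abs(bin_t) > guard_s
    admissible = np.flatnonzero(fits & outside_guard)
    if admissible.size == 0:
        raise ValueError("no admissible pseudo-onset times in this session")
    replace = admissible.size < n_null
    picks = rng.choice(admissible, size=n_null, replace=replace)

    p_null = np.stack([power[p + rel] for p in picks])
    p_real = power[det_idx]
    counts = (p_null >= p_real[None, :]).sum(axis=0)
    p_value = (1.0 + counts) / (n_null + 1.0)

    sig = np.flatnonzero(p_value < alpha)
    onset = float(bin_t[det_idx[sig[0]]]) if sig.size else None
    return SpectralOnset(
        bin_times_s=bin_t[det_idx],
        p_real=p_real,
        p_null=p_null,
        p_value=p_value,
        onset_time_s=onset,
        band_cpm=band_cpm,
        n_null=n_null,
        alpha=alpha,
    )


def psd_aperiodic_slope(
    fp: PhotometryTrace,
    baseline_window_s: tuple[float, float] = BASELINE_WINDOW_S,
    fit_band_cpm: tuple[float, float] = PSD_FIT_BAND_CPM,
    nperseg: int = 600,
) -> float:
    """Aperiodic exponent kappa of the baseline Welch PSD (1/f^kappa fit).

    Least-squares line in log-log space over the fit band; kappa is the
    negative of the fitted slope, so a larger kappa means a stronger
    low-frequency bias.  Invariant to vertical scaling of the trace.
    """
    base = fp.z.window_values(*baseline_window_s)
    if base.size < 20 * 60:
        raise ValueError("baseline must span at least 20 min for the PSD fit")
    freqs, psd = _sig.welch(base, fs=fp.z.fs, nperseg=min(nperseg, base.size))
    cpm = freqs * 60.0
    mask = (cpm >= fit_band_cpm[0]) & (cpm <= fit_band_cpm[1]) & (psd > 0)
    if mask.sum() < 2:
        raise ValueError("too few positive PSD points inside the fit band")
    slope = np.polyfit(np.log10(cpm[mask]), np.log10(psd[mask]), 1)[0]
    return float(-slope)
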