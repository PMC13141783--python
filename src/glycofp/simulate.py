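"""Seeded generator of paired photometry + glucose sessions.

The generator emulates the statistical structure the analysis pipeline
assumes, with stored ground truth for every session:

* **glycemia** — a dose-scaled smoothed-trapezoid excursion above a stable
  baseline.  Peak height and the rates of rise and fall all scale linearly
  with dose, so the rise and recovery *durations* are dose-invariant;
  additive Gaussian sensor noise and Poisson-timed telemetry spikes corrupt
  the observed trace.
* **neural activity** — an anticipatory "first-phase" inhibition whose onset
  precedes the gavage (mean -4 min, SD ~1 min) and whose amplitude is
  independent of dose, present only after prior glucose exposure; plus a
  "second-phase" inhibition proportional to the (rectified) glucose rate of
  change delayed by a positive lag (default +5 min), with a mirrored term
  during the decline.  The observed signal adds photobleaching drift, motion
  artifacts shared with the isosbestic reference channel, and white noise;
  the reference carries the shared components (scaled) plus independent
  noise.

Everything is reproducible from a master seed via spawned child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .io import Session, write_session
from .signal_core import UniformTrace

__all__ = [
    "GlycemiaParams",
    "NeuralParams",
    "CohortSpec",
    "simulate_bg",
    "simulate_fp",
    "generate_cohort",
]

SESSION_SPAN_S = (-25.0 * 60.0, 90.0 * 60.0)


@dataclass
class GlycemiaParams:
    """Parameters of the dose-scaled glucose excursion."""

    baseline: float = 130.0                 # mg/dL, 5-h-fasted arterial level
    dose: float = 2.0                       # g/kg
    rise_rate_per_dose: float = 6.0         # (mg/dL/min) per (g/kg)
    fall_rate_per_dose: float = 3.0         # (mg/dL/min) per (g/kg)
    peak_per_dose: float = 60.0             # mg/dL per (g/kg)
    onset_delay_min: float = 3.6            # min after gavage
    plateau_min: float = 5.0                # dwell at the peak, min
    noise_sd: float = 2.0                   # mg/dL
    spike_rate_per_min: float = 0.2         # telemetry dropout spikes
    spike_amp: float = 40.0                 # mg/dL, typical spike magnitude
    corner_smooth_s: int = 61               # centered boxcar on the clean shape


@dataclass
class NeuralParams:
    """Parameters of the two-phase neural response and its observation model."""

    phase1_amp: float = 2.0                 # inhibition depth, raw signal units
    phase1_onset_mean_min: float = -4.0     # min relative to gavage
    phase1_onset_sd_min: float = 1.0
    phase1_ramp_s: float = 120.0            # full duration of the decline ramp
    phase1_recovery_s: float = 2400.0       # relaxation, used when sustain < 1
    phase1_sustain_frac: float = 1.0        # fraction of depth held late
    phase1_dose_invariant: bool = True
    phase2_gain_rise: float = 0.12          # signal units per (mg/dL/min), rise
    phase2_gain_fall: float = 0.12          # same, applied to the decline
    phase2_lag_s: float = 300.0             # neural response lags dG/dt by this
    noise_sd: float = 0.3                   # white observation noise
    slow_noise_sd: float = 0.3              # slow baseline neural variability
    slow_noise_tau_s: float = 120.0         # its correlation time
    bleach_amp: float = 2.0                 # photobleaching drift amplitude
    bleach_tau_min: float = 15.0            # fastest right after illumination
    shared_ratio: float = 0.8               # artifact/bleach scale in reference
    artifact_rate_per_min: float = 0.5      # motion transients
    artifact_amp: float = 2.0
    artifact_decay_s: float = 2.0


@dataclass
class CohortSpec:
    """Design of a synthetic cohort: subjects x doses, randomized order."""

    n_subjects: int = 6
    doses: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 2.5)   # g/kg; 0 = water
    sessions_per_dose: int = 1
    span_s: tuple[float, float] = SESSION_SPAN_S
    master_seed: int = 0


def _time_grid(span_s: tuple[float, float]) -> np.ndarray:
    return np.arange(span_s[0], span_s[1] + 1.0)


def simulate_bg(
    params: GlycemiaParams,
    seed: int,
    span_s: tuple[float, float] = SESSION_SPAN_S,
) -> tuple[UniformTrace, dict]:
    """One glucose session; returns the noisy trace and its ground truth.

    The clean excursion is a trapezoid (linear rise at the dose-scaled rate
    to the dose-scaled peak, a plateau, then a linear fall back to baseline)
    with corners rounded by a short centered boxcar; a zero dose produces a
    flat baseline and an absent onset.
    """
    rng = np.random.default_rng(seed)
    t = _time_grid(span_s)
    dose = params.dose
    clean = np.full(t.size, params.baseline)
    truth: dict = {
        "dose": dose,
        "onset_time_s": None,
        "peak_delta_g": 0.0,
        "rise_rate_mg_dl_min": 0.0,
        "fall_rate_mg_dl_min": 0.0,
    }
    if dose > 0:
        peak = params.peak_per_dose * dose
        rise = params.rise_rate_per_dose * dose    # mg/dL/min
        fall = params.fall_rate_per_dose * dose
        if params.baseline - 0 < 0 or peak < 0:
            raise ValueError("parameters produce negative glucose")
        t_on = params.onset_delay_min * 60.0
        t_top = t_on + peak / rise * 60.0
        t_fall = t_top + params.plateau_min * 60.0
        t_end = t_fall + peak / fall * 60.0
        exc = np.interp(t, [t_on, t_top, t_fall, t_end], [0, peak, peak, 0],
                        left=0.0, right=0.0)
        if params.corner_smooth_s > 1:
            w = params.corner_smooth_s
            kern = np.ones(w) / w
            exc = np.convolve(exc, kern, mode="same")
        clean = params.baseline + exc
        truth.update(
            onset_time_s=float(t_on),
            peak_delta_g=float(peak),
            rise_rate_mg_dl_min=float(rise),
            fall_rate_mg_dl_min=float(fall),
        )
    if clean.min() < 0:
        raise ValueError("parameters produce negative glucose")

    observed = clean + rng.normal(0.0, params.noise_sd, t.size)
    n_spikes = rng.poisson(params.spike_rate_per_min * (t.size / 60.0))
    if n_spikes > 0:
        idx = rng.integers(0, t.size, n_spikes)
        amp = params.spike_amp * rng.choice([-1.0, 1.0], n_spikes) \
            * (0.5 + rng.random(n_spikes))
        observed[idx] += amp
    truth["clean"] = clean
    return UniformTrace(observed, t0=float(t[0])), truth


def _phase1_shape(t: np.ndarray, onset_s: float, params: NeuralParams) -> np.ndarray:
    """Unit-depth anticipatory inhibition: rapid finite ramp, sustained plateau.

    The decline is a smoothstep of duration ``phase1_ramp_s`` that reaches
    full depth exactly, after which the inhibition is held at
    ``phase1_sustain_frac`` of the depth (default 1: fully sustained within
    the session, so the early pattern is constant beyond its plateau); when
    the sustain fraction is below 1 the plateau is approached exponentially
    with ``phase1_recovery_s``.
    """
    dt = np.maximum(t - onset_s, 0.0)
    u = np.clip(dt / params.phase1_ramp_s, 0.0, 1.0)
    ramp = u * u * (3.0 - 2.0 * u)
    relax = params.phase1_sustain_frac + (1.0 - params.phase1_sustain_frac) \
        * np.exp(-np.maximum(dt - params.phase1_ramp_s, 0.0)
                 / params.phase1_recovery_s)
    return np.where(t >= onset_s, ramp * relax, 0.0)


def simulate_fp(
    bg_clean: np.ndarray,
    params: NeuralParams,
    dose: float,
    order_index: int,
    seed: int,
    span_s: tuple[float, float] = SESSION_SPAN_S,
    prior_exposure: Optional[bool] = None,
) -> tuple[UniformTrace, UniformTrace, dict]:
    """One photometry session driven by a clean glucose trace.

    Returns ``(signal, reference, truth)`` where the truth carries the clean
    neural trace and the phase parameters actually drawn.  The anticipatory
    first phase appears only for animals with prior glucose exposure
    (``order_index > 1`` unless overridden).
    """
    rng = np.random.default_rng(seed)
    t = _time_grid(span_s)
    if bg_clean.shape != t.shape:
        raise ValueError("bg_clean must be on the session time grid")
    anticipatory = prior_exposure if prior_exposure is not None else order_index > 1

    phase1 = np.zeros(t.size)
    onset_s = np.nan
    if anticipatory:
        onset_s = 60.0 * rng.normal(params.phase1_onset_mean_min,
                                    params.phase1_onset_sd_min)
        amp = params.phase1_amp
        if not params.phase1_dose_invariant:
            amp = amp * (0.5 + 0.5 * dose)
        phase1 = -amp * _phase1_shape(t, onset_s, params)

    # second phase: rectified, lagged glucose rate of change (per minute)
    dgdt = np.gradient(bg_clean) * 60.0           # mg/dL per min
    lag = int(round(params.phase2_lag_s))
    lagged = np.concatenate([np.zeros(lag), dgdt[: t.size - lag]]) if lag > 0 else dgdt
    # inhibition while glucose rises; recovery above the early-pattern
    # plateau while it falls — with equal gains this is a signed linear
    # response to the delayed rate of change
    phase2 = (-params.phase2_gain_rise * np.maximum(lagged, 0.0)
              + params.phase2_gain_fall * np.maximum(-lagged, 0.0))

    neural = phase1 + phase2

    bleach = params.bleach_amp * np.exp(-(t - t[0]) / (params.bleach_tau_min * 60.0))
    artifact = np.zeros(t.size)
    n_art = rng.poisson(params.artifact_rate_per_min * (t.size / 60.0))
    if n_art > 0:
        idx = rng.integers(0, t.size, n_art)
        amps = params.artifact_amp * rng.standard_normal(n_art)
        decay = np.exp(-np.arange(0, 8 * int(params.artifact_decay_s) + 1)
                       / params.artifact_decay_s)
        for i, a in zip(idx, amps):
            stop = min(t.size, i + decay.size)
            artifact[i:stop] += a * decay[: stop - i]

    # slow baseline neural variability (stationary Ornstein-Uhlenbeck):
    # gives the baseline window its low-frequency structure, so the
    # baseline SD (and hence the z-scale) is stable across sessions
    slow = np.zeros(t.size)
    if params.slow_noise_sd > 0:
        a = np.exp(-1.0 / params.slow_noise_tau_s)
        innov = rng.normal(0.0, 1.0, t.size)
        innov[0] /= np.sqrt(1.0 - a * a)   # stationary start
        slow = params.slow_noise_sd * np.sqrt(1.0 - a * a) \
            * _sig.lfilter([1.0], [1.0, -a], innov)

    shared = bleach + artifact
    signal = neural + slow + shared + rng.normal(0.0, params.noise_sd, t.size)
    reference = params.shared_ratio * shared \
        + rng.normal(0.0, params.noise_sd, t.size)
    truth = {
        "neural": neural,
        "phase1_onset_s": float(onset_s) if anticipatory else None,
        "phase1_amp": float(params.phase1_amp) if anticipatory else 0.0,
        "phase2_gain_rise": params.phase2_gain_rise,
        "phase2_gain_fall": params.phase2_gain_fall,
        "phase2_lag_s": params.phase2_lag_s,
        "anticipatory": bool(anticipatory),
    }
    t0 = float(t[0])
    return UniformTrace(signal, t0=t0), UniformTrace(reference, t0=t0), truth


def generate_cohort(
    spec: CohortSpec,
    glyc: Optional[GlycemiaParams] = None,
    neural: Optional[NeuralParams] = None,
    out_dir: Optional[Path] = None,
) -> tuple[list[Session], pd.DataFrame]:
    """A full cohort of sessions plus a ground-truth manifest.

    Dose order is randomized independently per subject, so the anticipatory
    phase (present from the second session on) is decoupled from dose.  With
    ``out_dir`` set, every session is written as CSV + sidecar JSON and the
    manifest as ``truth_manifest.tsv``; outputs are byte-identical for a
    given master seed.
    """
    glyc = glyc if glyc is not None else GlycemiaParams()
    neural = neural if neural is not None else NeuralParams()
    ss = np.random.SeedSequence(spec.master_seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])

    sessions: list[Session] = []
    rows: list[dict] = []
    seen: set[str] = set()
    for subj_i in range(spec.n_subjects):
        subject = f"m{subj_i + 1:02d}"
        dose_list = [d for d in spec.doses for _ in range(spec.sessions_per_dose)]
        order = order_rng.permutation(len(dose_list))
        for order_index, pos in enumerate(np.asarray(order), start=1):
            dose = float(dose_list[int(pos)])
            session_id = f"{subject}_s{order_index:02d}"
            if session_id in seen:
                raise ValueError(f"duplicate session id {session_id}")
            seen.add(session_id)
            child = ss.spawn(1)[0]
            bg_seed, fp_seed = child.generate_state(2) % (2 ** 31)
            gp = GlycemiaParams(**{**glyc.__dict__, "dose": dose})
            bg, bg_truth = simulate_bg(gp, int(bg_seed), span_s=spec.span_s)
            sig, ref, fp_truth = simulate_fp(
                bg_truth["clean"], neural, dose, order_index, int(fp_seed),
                span_s=spec.span_s,
            )
            sessions.append(Session(
                session_id=session_id,
                subject_id=subject,
                dose_g_per_kg=dose,
                route="OG",
                order_index=order_index,
                signal=sig,
                reference=ref,
                glucose=bg,
            ))
            rows.append({
                "session_id": session_id,
                "subject_id": subject,
                "dose_g_per_kg": dose,
                "order_index": order_index,
                "true_onset_time_s": bg_truth["onset_time_s"],
                "true_peak_delta_g": bg_truth["peak_delta_g"],
                "true_rise_rate_mg_dl_min": bg_truth["rise_rate_mg_dl_min"],
                "true_fall_rate_mg_dl_min": bg_truth["fall_rate_mg_dl_min"],
                "true_phase1_onset_s": fp_truth["phase1_onset_s"],
                "true_phase1_amp": fp_truth["phase1_amp"],
                "true_phase2_gain_rise": fp_truth["phase2_gain_rise"],
                "true_phase2_gain_fall": fp_truth["phase2_gain_fall"],
                "true_phase2_lag_s": fp_truth["phase2_lag_s"],
                "anticipatory": fp_truth["anticipatory"],
            })
            sessions[-1].truth = {
                "bg_clean": bg_truth["clean"],
                "neural": fp_truth["neural"],
                **{k: v for k, v in rows[-1].items() if k != "session_id"},
            }
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in sessions:
            write_session(s, out_dir / f"{s.session_id}.csv",
                          master_seed=spec.master_seed)
        manifest.to_csv(out_dir / "truth_manifest.tsv", sep="\t", index=False)
    return sessions, manifest
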