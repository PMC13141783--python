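"""Session file formats, run configuration, and the end-to-end pipeline.

A session on disk is a data CSV with columns ``time_s`` (seconds relative
to the gavage, strictly increasing at 1-s steps), ``fp_signal``,
``fp_reference`` and ``bg_mg_dl``, plus a sidecar JSON carrying the
metadata (subject, dose in g/kg, route, order index, units, seed).

``run_pipeline`` ties the stages together: glucose and photometry
preprocessing and metrics, the early-response model, lagged coupling with
pseudosession nulls, and the cohort statistics battery.  Every tunable is a
field of :class:`RunConfig`; a run log records the resolved configuration
and its hash so reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .signal_core import UniformTrace

logger = logging.getLogger("glycofp")

__all__ = [
    "Session",
    "RunConfig",
    "read_session",
    "write_session",
    "run_pipeline",
]


@dataclass
class Session:
    """Paired photometry (signal + reference) and glucose traces with metadata."""

    session_id: str
    subject_id: str
    dose_g_per_kg: float
    route: str                    # "OG" or "IP"
    order_index: int
    signal: UniformTrace
    reference: UniformTrace
    glucose: UniformTrace
    truth: Optional[dict] = None  # generator ground truth, if synthetic


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its default.

    Time windows named ``*_min`` are in minutes and converted exactly
    (x60) internally; windows named ``*_s`` are in seconds.
    """

    # shared preprocessing
    despike_k: float = 2.0
    despike_detrend_window: int = 31
    median_window: int = 7
    smooth_window: int = 60
    baseline_window_min: tuple[float, float] = (-25.0, 0.0)
    # glucose
    boxcar_window: int = 120
    onset_baseline_window_min: tuple[float, float] = (-5.0, 0.0)
    onset_z: float = 3.0
    onset_sustain_s: int = 60
    plateau_band_frac: float = 0.1
    plateau_sustain_s: int = 120
    # photometry
    lowpass_period_min: float = 4.0
    lowpass_order: int = 3
    peak_z_window_min: tuple[float, float] = (0.0, 15.0)
    peak_z_direction: str = "inhibition"
    spectral_n_null: int = 200
    spectral_guard_min: float = 5.0
    spectral_alpha: float = 0.05
    spectral_detect_window_min: tuple[float, float] = (-10.0, 10.0)
    psd_fit_band_cpm: tuple[float, float] = (0.05, 0.5)
    # early-response model
    tau_grid_min: tuple[float, ...] = tuple(np.arange(-1.0, 1.01, 0.25))
    cv_folds: int = 5
    train_doses: tuple[float, ...] = (1.0, 2.0, 2.5)
    model_window_min: tuple[float, float] = (-25.0, 1.0)
    residual_windows_min: tuple[tuple[float, float], ...] = ((0.0, 10.0),
                                                            (10.0, 60.0))
    # coupling
    max_lag_min: float = 20.0
    lag_step_s: float = 1.0
    n_null_pairings: int = 100
    min_offset_min: float = 20.0
    coupling_alpha: float = 0.01
    coupling_window_min: tuple[float, float] = (0.0, 90.0)
    coupling_dose: Optional[float] = 2.0
    # randomness
    seed: int = 0

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return json.loads(json.dumps(out))  # tuples -> lists, plain types

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if isinstance(v, list):
                v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# session files
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("time_s", "fp_signal", "fp_reference", "bg_mg_dl")


def write_session(session: Session, csv_path: Path,
                  master_seed: Optional[int] = None) -> None:
    """Write a session as data CSV + sidecar metadata JSON (lossless)."""
    csv_path = Path(csv_path)
    df = pd.DataFrame({
        "time_s": session.glucose.t,
        "fp_signal": session.signal.values,
        "fp_reference": session.reference.values,
        "bg_mg_dl": session.glucose.values,
    })
    df.to_csv(csv_path, index=False, float_format="%.10g")
    meta = {
        "session_id": session.session_id,
        "subject_id": session.subject_id,
        "dose_g_per_kg": session.dose_g_per_kg,
        "route": session.route,
        "order_index": session.order_index,
        "units": {"time_s": "s", "bg_mg_dl": "mg/dL",
                  "fp_signal": "a.u.", "fp_reference": "a.u."},
    }
    if master_seed is not None:
        meta["master_seed"] = master_seed
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_session(csv_path: Path) -> Session:
    """Read and validate a session CSV + sidecar JSON."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{csv_path.name}: missing column '{col}'")
        bad = df.index[df[col].isna()]
        if bad.size:
            raise ValueError(
                f"{csv_path.name}: NaN in column '{col}' at row {bad[0]}"
            )
    t = df["time_s"].to_numpy(dtype=float)
    steps = np.diff(t)
    off = np.flatnonzero(np.abs(steps - 1.0) > 1e-6)
    if off.size:
        raise ValueError(
            f"{csv_path.name}: non-uniform time grid at row {off[0] + 1} "
            f"(step {steps[off[0]]:.6g} s)"
        )
    meta_path = csv_path.with_suffix(".json")
    if not meta_path.exists():
        raise ValueError(f"{csv_path.name}: sidecar JSON {meta_path.name} missing")
    meta = json.loads(meta_path.read_text())
    dose = float(meta["dose_g_per_kg"])
    if dose < 0:
        raise ValueError(f"{csv_path.name}: negative dose")
    t0 = float(t[0])
    return Session(
        session_id=str(meta.get("session_id", csv_path.stem)),
        subject_id=str(meta["subject_id"]),
        dose_g_per_kg=dose,
        route=str(meta.get("route", "OG")),
        order_index=int(meta.get("order_index", 1)),
        signal=UniformTrace(df["fp_signal"].to_numpy(dtype=float), t0=t0),
        reference=UniformTrace(df["fp_reference"].to_numpy(dtype=float), t0=t0),
        glucose=UniformTrace(df["bg_mg_dl"].to_numpy(dtype=float), t0=t0),
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _window_s(window_min: tuple[float, float]) -> tuple[float, float]:
    return (window_min[0] * 60.0, window_min[1] * 60.0)


def _slice_trace(trace: UniformTrace, window_s: tuple[float, float]) -> UniformTrace:
    mask = trace.window_mask(*window_s)
    idx = np.flatnonzero(mask)
    return UniformTrace(trace.values[idx[0]: idx[-1] + 1],
                        t0=float(trace.t[idx[0]]), fs=trace.fs)


def process_session(session: Session, config: RunConfig,
                    rng: np.random.Generator) -> dict:
    """Preprocess one session and compute its per-session metrics row."""
    from . import glucose as glu
    from . import photometry as phot

    base_s = _window_s(config.baseline_window_min)
    g = glu.preprocess_glucose(
        session.glucose,
        despike_k=config.despike_k,
        despike_detrend_window=config.despike_detrend_window,
        median_window=config.median_window,
        smooth_window=config.smooth_window,
        boxcar_window=config.boxcar_window,
        baseline_window_s=base_s,
        onset_baseline_window_s=_window_s(config.onset_baseline_window_min),
    )
    thresholds = glu.compute_onset_thresholds(g, z=config.onset_z)
    onset = glu.detect_bg_onset(g, thresholds, sustain_s=config.onset_sustain_s)
    gm = glu.excursion_summary(
        g, onset,
        plateau_band_frac=config.plateau_band_frac,
        plateau_sustain_s=config.plateau_sustain_s,
    )
    fp = phot.preprocess_photometry(
        session.signal, session.reference,
        despike_k=config.despike_k,
        despike_detrend_window=config.despike_detrend_window,
        median_window=config.median_window,
        smooth_window=config.smooth_window,
        lowpass_period_min=config.lowpass_period_min,
        lowpass_order=config.lowpass_order,
        baseline_window_s=base_s,
        label=session.session_id,
    )
    peak_z, peak_z_t = phot.peak_z_response(
        fp, _window_s(config.peak_z_window_min), config.peak_z_direction
    )
    has_excursion = gm.peak_delta_g > 0 and gm.onset_time_s is not None
    neg = phot.negative_auc(fp, gm.peak_time_s) if has_excursion else None
    onset_spec = phot.band_power_onset(
        fp,
        n_null=config.spectral_n_null,
        guard_s=config.spectral_guard_min * 60.0,
        detect_window_s=_window_s(config.spectral_detect_window_min),
        alpha=config.spectral_alpha,
        rng=rng,
    )
    kappa = phot.psd_aperiodic_slope(fp, base_s, config.psd_fit_band_cpm)

    # rate of fall: steepest decline of the smoothed derivative after the peak
    post_peak = g.derivative.window_mask(gm.peak_time_s, _window_s(
        config.coupling_window_min)[1])
    fall_rate = float(-np.min(g.derivative.values[post_peak]) * 60.0) \
        if post_peak.any() else np.nan

    row = {
        "session_id": session.session_id,
        "subject": session.subject_id,
        "dose": session.dose_g_per_kg,
        "order_index": session.order_index,
        "route": session.route,
        "baseline_value": gm.baseline_value,
        "onset_time_s": gm.onset_time_s,
        "peak_delta_g": gm.peak_delta_g,
        "peak_time_s": gm.peak_time_s,
        "peak_derivative": gm.peak_derivative * 60.0,   # mg/dL per min
        "peak_derivative_time_s": gm.peak_derivative_time_s,
        "fall_rate": fall_rate,                          # mg/dL per min
        "half_max_return_time_s": gm.half_max_return_time_s,
        "return_to_baseline_time_s": gm.return_to_baseline_time_s,
        "iauc_mg_dl_min": gm.iauc_mg_dl_min,
        "peak_z_early": peak_z,
        "peak_z_early_time_s": peak_z_t,
        "neg_auc_z_min": neg,
        "total_auc_z_min": phot.total_auc(fp),
        "psd_slope": kappa,
        "spectral_onset_s": onset_spec.onset_time_s,
    }
    return {"row": row, "glucose": g, "photometry": fp, "metrics": gm}


def run_pipeline(cohort_dir: Path, config: RunConfig, out_dir: Path,
                 stages: tuple[str, ...] = ("model", "coupling", "stats"),
                 ) -> Path:
    """Run the pipeline on a cohort directory; returns the results directory.

    Produces ``session_metrics.tsv``, per-session early-model JSONs and
    residual CSVs, a template CSV, correlogram and group-coupling CSVs, a
    ``statistics.tsv`` battery, and ``run_log.json`` with the resolved
    config, its hash and the master seed.  Per-session failures are logged
    and skipped; the run fails only if every session fails.

    ``stages`` selects the optional stages: preprocessing and per-session
    metrics always run (everything depends on them); ``"model"`` adds the
    early-response model, ``"coupling"`` the lagged coupling analysis
    (requires ``"model"``), ``"stats"`` the cohort statistics battery.
    """
    from . import coupling as cpl
    from . import early_response as erm
    from . import stats as st

    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(cohort_dir.glob("*.csv"))
    paths = [p for p in paths if not p.name.startswith("truth_manifest")]
    if not paths:
        raise FileNotFoundError(f"no session CSVs found in {cohort_dir}")

    master = np.random.SeedSequence(config.seed)
    spectral_rng = np.random.default_rng(master.spawn(1)[0])
    coupling_rng = np.random.default_rng(master.spawn(1)[0])

    processed: dict[str, dict] = {}
    failures: dict[str, str] = {}
    sessions: dict[str, Session] = {}
    for p in paths:
        try:
            s = read_session(p)
            processed[s.session_id] = process_session(s, config, spectral_rng)
            sessions[s.session_id] = s
        except Exception as exc:  # noqa: BLE001 - per-session isolation
            failures[p.name] = str(exc)
            logger.warning("session %s failed: %s", p.name, exc)
    if not processed:
        raise RuntimeError(f"all sessions failed: {failures}")

    rows = [v["row"] for v in processed.values()]
    table = pd.DataFrame(rows)

    # ---- early-response model -------------------------------------------
    model_window = _window_s(config.model_window_min)
    train = [
        (sid, sessions[sid].subject_id, processed[sid]["photometry"].z)
        for sid in processed
        if sessions[sid].dose_g_per_kg in config.train_doses
    ]
    fits: dict[str, erm.EarlyResponseFit] = {}
    if "model" in stages and len(train) >= 2:
        plan = erm.make_cv_plan(
            [sid for sid, _, _ in train], [subj for _, subj, _ in train],
            k=max(2, min(config.cv_folds, len(train))),
            tau_grid_min=config.tau_grid_min,
        )
        tau_star, cv_r2, _ = erm.select_lag_cv(train, plan, model_window)
        template = erm.build_template(
            [(sid, z) for sid, _, z in train], model_window,
            dose_set=config.train_doses,
        )
        pd.DataFrame({"time_s": template.t, "template_z": template.values}) \
            .to_csv(out_dir / "template.csv", index=False)
        model_dir = out_dir / "early_model"
        model_dir.mkdir(exist_ok=True)
        for sid, v in processed.items():
            # each session is allowed its own small temporal shift within
            # the CV-validated grid; tau_star summarizes the cohort
            tau_i = erm.select_session_lag(
                v["photometry"].z, template, config.tau_grid_min,
                model_window,
            )
            fit = erm.predict_and_residual(
                sid, v["photometry"].z, template, tau_i, model_window,
                cv_r2=cv_r2,
            )
            fits[sid] = fit
            summary = erm.summarize_residual(fit, config.residual_windows_min)
            (model_dir / f"{sid}.json").write_text(json.dumps({
                "session_id": sid, "beta0": fit.beta0, "beta1": fit.beta1,
                "tau_min": fit.tau_min, "mse": fit.mse, "r2": fit.r2,
                "cv_r2": fit.cv_r2, **summary,
            }, indent=1))
            pd.DataFrame({
                "time_s": fit.residual.t,
                "z": v["photometry"].z.values,
                "prediction": fit.prediction.values,
                "residual": fit.residual.values,
            }).to_csv(model_dir / f"{sid}_traces.csv", index=False,
                      float_format="%.8g")
        table["beta0"] = table["session_id"].map(
            {sid: f.beta0 for sid, f in fits.items()})
        table["beta1"] = table["session_id"].map(
            {sid: f.beta1 for sid, f in fits.items()})
        table["tau_min"] = table["session_id"].map(
            {sid: f.tau_min for sid, f in fits.items()})
        table["tau_star_min"] = tau_star
        late = {sid: erm.summarize_residual(f, config.residual_windows_min)
                for sid, f in fits.items()}
        tag = f"{config.residual_windows_min[-1][0]:g}_" \
              f"{config.residual_windows_min[-1][1]:g}"
        table["residual_min_late"] = table["session_id"].map(
            {sid: s[f"min_{tag}"] for sid, s in late.items()})
        table["residual_mean_late"] = table["session_id"].map(
            {sid: s[f"mean_{tag}"] for sid, s in late.items()})

    table.to_csv(out_dir / "session_metrics.tsv", sep="\t", index=False)

    # ---- coupling --------------------------------------------------------
    couple_ids = [
        sid for sid in processed
        if config.coupling_dose is None
        or sessions[sid].dose_g_per_kg == config.coupling_dose
    ]
    window = _window_s(config.coupling_window_min)
    if "coupling" in stages and len(couple_ids) >= 3 and fits:
        coupling_dir = out_dir / "coupling"
        coupling_dir.mkdir(exist_ok=True)
        real_res, real_pred, nulls = [], [], []
        peaks_pred: dict[str, float] = {}
        peaks_res: dict[str, float] = {}
        bg_by_sid = {
            sid: _slice_trace(processed[sid]["glucose"].derivative, window)
            for sid in couple_ids
        }
        for sid in couple_ids:
            bg_d = bg_by_sid[sid]
            resid = _slice_trace(fits[sid].residual, window)
            pred = _slice_trace(fits[sid].prediction, window)
            cg_res = cpl.lagged_spearman(
                resid, bg_d, config.max_lag_min * 60.0, config.lag_step_s)
            cg_pred = cpl.lagged_spearman(
                pred, bg_d, config.max_lag_min * 60.0, config.lag_step_s)
            real_res.append(cg_res)
            real_pred.append(cg_pred)
            if cg_res.peak_lag_s is not None:
                peaks_res[sid] = cg_res.peak_lag_s
            if cg_pred.peak_lag_s is not None:
                peaks_pred[sid] = cg_pred.peak_lag_s
            others = [bg_by_sid[o] for o in couple_ids if o != sid]
            nulls.append(cpl.pseudosession_null(
                resid, others, config.n_null_pairings,
                config.min_offset_min * 60.0, coupling_rng,
                config.max_lag_min * 60.0, config.lag_step_s,
            ))
            pd.DataFrame({
                "lag_s": cg_res.lags_s, "rho_residual": cg_res.rho,
                "rho_prediction": cg_pred.rho,
            }).to_csv(coupling_dir / f"{sid}_correlogram.csv", index=False,
                      float_format="%.8g")
        group = cpl.group_significance(real_res, nulls, config.coupling_alpha)
        pd.DataFrame({
            "lag_s": group.lags_s, "mean_rho": group.mean_rho,
            "p_raw": group.p_raw, "p_bh": group.p_bh,
            "significant": group.significant,
        }).to_csv(coupling_dir / "group_residual_vs_derivative.csv",
                  index=False, float_format="%.8g")
        if len(set(peaks_pred) & set(peaks_res)) >= 2:
            cmp_res = cpl.peak_lag_compare(peaks_pred, peaks_res)
            (coupling_dir / "peak_lag_compare.json").write_text(json.dumps({
                "median_diff_s": cmp_res["median_diff_s"],
                "statistic": cmp_res["statistic"],
                "p_value": cmp_res["p_value"],
                "n": len(cmp_res["session_ids"]),
            }, indent=1))

    # ---- cohort statistics ----------------------------------------------
    extra: dict = {}
    if "stats" in stages:
        battery = st.dose_metric_correlations(table)
        battery.to_csv(out_dir / "statistics.tsv", sep="\t", index=False)
        onsets = table.loc[table["order_index"] > 1,
                           "spectral_onset_s"].dropna()
        if onsets.size >= 3:
            extra["anticipatory_onset_test"] = st.onset_sign_test(
                onsets.to_numpy() / 60.0)

    (out_dir / "run_log.json").write_text(json.dumps({
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_sessions": len(processed),
        "failures": failures,
        **extra,
    }, indent=1, default=float))
    return out_dir
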