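"""Lagged template regression separating the anticipatory early response
from later, glycemia-coupled activity.

The early, stimulus-locked component of the photometry response is modeled
per session as an affine transform of a cross-session template shifted by a
small lag:

    F_hat_i(t; tau) = beta0_i + beta1_i * template(t - tau),  t in [-25, +1] min

The template is the pointwise across-session median of the training
sessions' z-scored traces over the model window (robust to outliers).  The
lag ``tau`` is shared across sessions and selected on a small grid
(-1 to +1 min in 0.25-min steps) by K-fold cross-validation over training
sessions, with folds stratified by subject; per-session (beta0, beta1) are
then refit at the selected lag.  Only data up to +1 min after the gavage
ever enters a fit — the residual ``R_i(t) = Z_i(t) - F_hat_i(t)`` over later
times therefore quantifies activity the early template cannot explain.

Beyond +1 min the prediction holds the template's final value constant, so
late residuals read as deviation from the early pattern's plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .signal_core import UniformTrace

__all__ = [
    "MODEL_WINDOW_S",
    "DEFAULT_TAU_GRID_MIN",
    "EarlyTemplate",
    "EarlyResponseFit",
    "CvPlan",
    "make_cv_plan",
    "build_template",
    "fit_session",
    "select_lag_cv",
    "select_session_lag",
    "predict_and_residual",
    "summarize_residual",
]

MODEL_WINDOW_S = (-25.0 * 60.0, 1.0 * 60.0)
#: candidate lags in minutes: -1.00, -0.75, ..., +1.00
DEFAULT_TAU_GRID_MIN: tuple[float, ...] = tuple(np.arange(-1.0, 1.01, 0.25))


@dataclass
class EarlyTemplate:
    """Across-session median early-response template on the model-window grid."""

    values: np.ndarray          # z-units, one sample per second
    t0: float                   # s, start of the model window
    fs: float = 1.0
    n_sessions: int = 0
    dose_set: tuple[float, ...] = ()

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def shifted_values(self, tau_min: float, t_query: np.ndarray) -> np.ndarray:
        """Template evaluated at t_query - tau, nearest-edge filled outside."""
        shift_samples = tau_min * 60.0 * self.fs
        idx = np.round((t_query - self.t0) * self.fs - shift_samples).astype(int)
        idx = np.clip(idx, 0, self.values.size - 1)
        return self.values[idx]


@dataclass
class EarlyResponseFit:
    """Per-session early-response fit, prediction and residual."""

    session_id: str
    beta0: float                 # intercept, z-units
    beta1: float                 # slope/scale, unitless
    tau_min: float               # selected lag, minutes
    mse: float                   # fit-window mean squared error
    r2: float                    # fit-window R^2
    cv_r2: Optional[float]       # mean validation R^2 at the selected lag
    prediction: UniformTrace
    residual: UniformTrace


@dataclass
class CvPlan:
    """K-fold assignment of training sessions, stratified by subject."""

    k: int
    fold_of_session: dict[str, int]
    tau_grid_min: tuple[float, ...] = DEFAULT_TAU_GRID_MIN


def make_cv_plan(
    session_ids: Sequence[str],
    subjects: Sequence[str],
    k: int = 5,
    tau_grid_min: Sequence[float] = DEFAULT_TAU_GRID_MIN,
) -> CvPlan:
    """Assign sessions to K folds, keeping each subject's sessions together.

    Subjects are distributed round-robin over folds (largest first for
    balance).  With a single subject, stratification is impossible and plain
    session-level K-fold is used instead.
    """
    if k < 2:
        raise ValueError("K-fold cross-validation requires K >= 2")
    session_ids = list(session_ids)
    subjects = list(subjects)
    uniq = sorted(set(subjects))
    fold_of_session: dict[str, int] = {}
    if len(uniq) == 1:
        for i, sid in enumerate(session_ids):
            fold_of_session[sid] = i % k
    else:
        counts = {s: subjects.count(s) for s in uniq}
        ordered = sorted(uniq, key=lambda s: (-counts[s], s))
        fold_of_subject = {s: i % k for i, s in enumerate(ordered)}
        for sid, subj in zip(session_ids, subjects):
            fold_of_session[sid] = fold_of_subject[subj]
    return CvPlan(k=k, fold_of_session=fold_of_session,
                  tau_grid_min=tuple(tau_grid_min))


def _window_grid(window_s: tuple[float, float]) -> np.ndarray:
    """The common 1 Hz grid over a closed-open model window."""
    return np.arange(window_s[0], window_s[1])


def build_template(
    training_sessions: Sequence[tuple[str, UniformTrace]],
    window_s: tuple[float, float] = MODEL_WINDOW_S,
    dose_set: tuple[float, ...] = (),
) -> EarlyTemplate:
    """Pointwise across-session median over the model window.

    Sessions lacking full coverage of the window are excluded; excluding all
    sessions is an error.  ``training_sessions`` pairs a session id with its
    z-scored photometry trace.
    """
    grid = _window_grid(window_s)
    rows = []
    for sid, z in training_sessions:
        if z.t0 > grid[0] or z.t[-1] < grid[-1]:
            continue
        start = z.index_of_time(grid[0])
        rows.append(z.values[start: start + grid.size])
    if len(rows) < 2:
        raise ValueError(
            "need at least 2 sessions covering the model window to build a template"
        )
    stack = np.vstack(rows)
    return EarlyTemplate(
        values=np.median(stack, axis=0),
        t0=float(grid[0]),
        n_sessions=stack.shape[0],
        dose_set=tuple(dose_set),
    )


def fit_session(
    z: UniformTrace,
    template: EarlyTemplate,
    tau_min: float,
    fit_window_s: tuple[float, float] = MODEL_WINDOW_S,
) -> tuple[float, float, float, float]:
    """OLS of the session on the lag-shifted template over the fit window.

    Returns ``(beta0, beta1, mse, r2)``.  No sample after the end of the fit
    window enters the regression.
    """
    grid = _window_grid(fit_window_s)
    if z.t0 > grid[0] or z.t[-1] < grid[-1]:
        raise ValueError("session does not cover the fit window")
    start = z.index_of_time(grid[0])
    y = z.values[start: start + grid.size]
    x = template.shifted_values(tau_min, grid)
    if np.ptp(x) == 0:
        raise ValueError("shifted template is constant over the fit window")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ coef
    resid = y - pred
    mse = float(np.mean(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return float(coef[0]), float(coef[1]), mse, r2


def select_lag_cv(
    training_sessions: Sequence[tuple[str, str, UniformTrace]],
    plan: CvPlan,
    fit_window_s: tuple[float, float] = MODEL_WINDOW_S,
) -> tuple[float, float, dict[float, float]]:
    """Cross-validated lag selection.

    ``training_sessions`` is a sequence of (session_id, subject, z-trace).
    For each candidate lag the template is rebuilt from K-1 folds, left-out
    sessions are fit, and validation MSE accumulated.  Returns
    ``(tau_star, cv_r2_at_tau_star, mse_by_tau)``; ties on MSE break to the
    higher mean validation R^2, then to the smaller absolute lag.
    """
    folds = sorted({plan.fold_of_session[sid] for sid, _, _ in training_sessions})
    if len(folds) < 2:
        raise ValueError("cross-validation requires at least 2 non-empty folds")
    mse_by_tau: dict[float, float] = {}
    r2_by_tau: dict[float, float] = {}
    for tau in plan.tau_grid_min:
        errs: list[float] = []
        r2s: list[float] = []
        for k in folds:
            train = [(sid, z) for sid, _, z in training_sessions
                     if plan.fold_of_session[sid] != k]
            val = [(sid, z) for sid, _, z in training_sessions
                   if plan.fold_of_session[sid] == k]
            if not train or not val:
                continue
            if len(train) < 2:
                # a lone training session is its own (degenerate) template
                tmpl = build_template(train * 2, fit_window_s)
            else:
                tmpl = build_template(train, fit_window_s)
            for sid, z in val:
                _, _, mse, r2 = fit_session(z, tmpl, tau, fit_window_s)
                errs.append(mse)
                r2s.append(r2)
        mse_by_tau[tau] = float(np.mean(errs))
        r2_by_tau[tau] = float(np.mean(r2s))
    # argmin MSE; ties -> higher R^2 -> smaller |tau|
    def key(tau: float) -> tuple[float, float, float]:
        return (round(mse_by_tau[tau], 12), -round(r2_by_tau[tau], 12), abs(tau))

    tau_star = min(plan.tau_grid_min, key=key)
    return float(tau_star), r2_by_tau[tau_star], mse_by_tau


def select_session_lag(
    z: UniformTrace,
    template: EarlyTemplate,
    tau_grid_min: Sequence[float] = DEFAULT_TAU_GRID_MIN,
    fit_window_s: tuple[float, float] = MODEL_WINDOW_S,
) -> float:
    """Per-session temporal shift: the grid lag minimizing fit-window MSE.

    The template regression allows each session a small temporal shift so
    that session-to-session variation in anticipatory onset (about +/-1 min)
    does not attenuate the fitted scale.  Uses only the fit window, with the
    same tie-break rule as the cross-validated selection (higher R^2, then
    smaller absolute lag).
    """
    scores: dict[float, tuple[float, float, float]] = {}
    for tau in tau_grid_min:
        _, _, mse, r2 = fit_session(z, template, tau, fit_window_s)
        scores[float(tau)] = (round(mse, 12), -round(r2, 12), abs(tau))
    return float(min(scores, key=scores.get))


def predict_and_residual(
    session_id: str,
    z: UniformTrace,
    template: EarlyTemplate,
    tau_star_min: float,
    fit_window_s: tuple[float, float] = MODEL_WINDOW_S,
    cv_r2: Optional[float] = None,
) -> EarlyResponseFit:
    """Refit (beta0, beta1) at the selected lag and extend over the session.

    The prediction evaluates ``beta0 + beta1 * template(t - tau*)`` over the
    whole session time axis; outside the (shifted) template support the
    nearest edge value is held constant, so beyond +1 min the prediction is
    the template's plateau.  The residual is the pointwise difference.
    """
    beta0, beta1, mse, r2 = fit_session(z, template, tau_star_min, fit_window_s)
    pred_vals = beta0 + beta1 * template.shifted_values(tau_star_min, z.t)
    prediction = z.with_values(pred_vals)
    residual = z.with_values(z.values - pred_vals)
    return EarlyResponseFit(
        session_id=session_id,
        beta0=beta0,
        beta1=beta1,
        tau_min=tau_star_min,
        mse=mse,
        r2=r2,
        cv_r2=cv_r2,
        prediction=prediction,
        residual=residual,
    )


def summarize_residual(
    fit: EarlyResponseFit,
    windows_min: Sequence[tuple[float, float]] = ((0.0, 10.0), (10.0, 60.0)),
) -> dict[str, float]:
    """Mean and extremal residual (with time) per analysis window.

    Keys are ``mean_<a>_<b>``, ``min_<a>_<b>`` and ``min_time_<a>_<b>`` with
    the window bounds in minutes; the extremum is the most negative residual
    (peak residual inhibition), whose time supports timing comparisons.
    """
    out: dict[str, float] = {}
    r = fit.residual
    for a, b in windows_min:
        mask = r.window_mask(a * 60.0, b * 60.0)
        if not mask.any():
            raise ValueError(f"residual window [{a}, {b}] min outside session")
        vals = r.values[mask]
        times = r.t[mask]
        idx = int(np.argmin(vals))
        tag = f"{a:g}_{b:g}"
        out[f"mean_{tag}"] = float(vals.mean())
        out[f"min_{tag}"] = float(vals[idx])
        out[f"min_time_{tag}"] = float(times[idx])
    return out
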