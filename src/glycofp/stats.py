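"""Cohort-level statistics: timing tests and fixed-effects regressions.

The experimental unit throughout is the session.  Paired timing comparisons
use the two-sided Wilcoxon signed-rank test; anticipatory-onset sign tests
use a one-sample Student's t.  Continuous relationships are evaluated by
ordinary least squares with subject fixed effects (indicator variables),
optional covariates (dose, baseline glucose), and heteroskedasticity-robust
(HC3) standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
import statsmodels.formula.api as smf

__all__ = [
    "RegressionResult",
    "ols_fixed_effects",
    "paired_timing_test",
    "onset_sign_test",
    "dose_metric_correlations",
]


@dataclass
class RegressionResult:
    """Slope of interest from a fixed-effects OLS fit with robust SE."""

    name: str
    slope: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    r_squared: float
    n: int
    covariates: tuple[str, ...]

    def to_row(self) -> dict:
        return {
            "name": self.name,
            "slope": self.slope,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "r_squared": self.r_squared,
            "n": self.n,
            "covariates": "+".join(self.covariates) if self.covariates else "",
        }


def ols_fixed_effects(
    table: pd.DataFrame,
    y: str,
    x: str,
    subject: str = "subject",
    covariates: Sequence[str] = (),
    name: Optional[str] = None,
) -> RegressionResult:
    """OLS of y on x with subject fixed effects and HC3 robust errors.

    With a single subject the fixed effects collapse to the intercept and
    the fit reduces to plain OLS.  Collinear designs raise with the
    offending terms named.
    """
    cols = [y, x, subject, *covariates]
    data = table[cols].dropna()
    n_subjects = data[subject].nunique()
    terms = [x] + list(covariates)
    if n_subjects > 1:
        terms.append(f"C({subject})")
    formula = f"{y} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(
            f"collinear design in '{formula}': columns {model.exog_names}"
        )
    if data.shape[0] <= model.exog.shape[1]:
        raise ValueError("more parameters than observations")
    fit = model.fit(cov_type="HC3")
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        name=name or f"{y}~{x}",
        slope=float(fit.params[x]),
        se=float(fit.bse[x]),
        ci_low=float(ci.loc[x, 0]),
        ci_high=float(ci.loc[x, 1]),
        p_value=float(fit.pvalues[x]),
        r_squared=float(fit.rsquared),
        n=int(data.shape[0]),
        covariates=tuple(covariates),
    )


def paired_timing_test(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired event times.

    Zero differences are dropped (the classic convention); if every
    difference is zero the comparison is degenerate and p = 1 is reported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = b - a
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 0.0, 1.0
    res = _stats.wilcoxon(nonzero, alternative="two-sided",
                          zero_method="wilcox", mode="auto")
    return float(res.statistic), float(res.pvalue)


def onset_sign_test(onset_times: np.ndarray) -> dict:
    """One-sample two-sided t test of onset times against zero.

    Returns the t statistic, p-value, and mean +/- SEM.  Zero variance is a
    degenerate case flagged in the result rather than an exception.
    """
    x = np.asarray(onset_times, dtype=float)
    if x.size < 3:
        raise ValueError("one-sample t test needs at least 3 onsets")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    sem = sd / np.sqrt(x.size)
    if sd == 0:
        return {"t": np.nan, "p": np.nan, "mean": mean, "sem": 0.0,
                "n": int(x.size), "degenerate": True}
    res = _stats.ttest_1samp(x, 0.0)
    return {"t": float(res.statistic), "p": float(res.pvalue), "mean": mean,
            "sem": float(sem), "n": int(x.size), "degenerate": False}


#: regressions of the standard cohort battery: (name, response, predictor)
_BATTERY: tuple[tuple[str, str, str], ...] = (
    ("peak_delta_g_vs_dose", "peak_delta_g", "dose"),
    ("rise_rate_vs_dose", "peak_derivative", "dose"),
    ("fall_rate_vs_dose", "fall_rate", "dose"),
    ("iauc_vs_dose", "iauc_mg_dl_min", "dose"),
    ("peak_inhibition_vs_dose", "peak_z_early", "dose"),
    ("peak_inhibition_vs_peak_dg", "peak_z_early", "peak_delta_g"),
    ("peak_inhibition_vs_rise_rate", "peak_z_early", "peak_derivative"),
    ("peak_inhibition_vs_fall_rate", "peak_z_early", "fall_rate"),
    ("neg_auc_vs_dose", "neg_auc_z_min", "dose"),
    ("residual_min_vs_peak_dg", "residual_min_late", "peak_delta_g"),
    ("residual_min_vs_rise_rate", "residual_min_late", "peak_derivative"),
    ("residual_min_vs_fall_rate", "residual_min_late", "fall_rate"),
    ("beta1_vs_rise_rate", "peak_derivative", "beta1"),
    ("beta1_vs_fall_rate", "fall_rate", "beta1"),
)


def dose_metric_correlations(
    table: pd.DataFrame, subject: str = "subject"
) -> pd.DataFrame:
    """The standard battery of cohort regressions as a tidy result table.

    Fits every battery entry whose response and predictor columns are
    present (with at least 3 complete rows); the slope-state regressions
    (beta1 against glycemic rates) additionally adjust for dose and baseline
    glucose when available.  Deterministic given the input table.
    """
    rows = []
    for name, y, x in _BATTERY:
        if y not in table.columns or x not in table.columns:
            continue
        covs: list[str] = []
        if name.startswith("beta1_"):
            covs = [c for c in ("dose", "baseline_value") if c in table.columns
                    and c not in (x, y)]
        sub = table[[y, x, subject, *covs]].dropna()
        if sub.shape[0] < 3 or sub[x].nunique() < 2:
            continue
        try:
            res = ols_fixed_effects(sub, y, x, subject=subject,
                                    covariates=covs, name=name)
        except ValueError:
            continue
        rows.append(res.to_row())
    return pd.DataFrame(rows)
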