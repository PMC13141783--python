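"""Time-lagged rank correlation between photometry and glucose with
pseudosession nulls.

For each lag L (seconds; **positive lag means the photometry follows the
glucose**), the overlapping segments of the two series are rank-transformed
and their Pearson correlation computed (Spearman's rho).  Specificity is
assessed against pseudosession nulls built by pairing a session's photometry
with circularly shifted glucose traces from *other* sessions (minimum shift
20 min), which preserves each series' autocorrelation while destroying any
true pairing.  Group summaries average per-session correlations in Fisher-z
space and control the false discovery rate across lags with the
Benjamini-Hochberg procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .signal_core import UniformTrace

__all__ = [
    "Correlogram",
    "NullEnsemble",
    "GroupCorrelogram",
    "lagged_spearman",
    "pseudosession_null",
    "group_significance",
    "peak_lag_compare",
]

MIN_OVERLAP_SAMPLES = 120
DEFAULT_MAX_LAG_S = 20.0 * 60.0
DEFAULT_MIN_OFFSET_S = 20.0 * 60.0


@dataclass
class Correlogram:
    """Spearman correlation by lag for one photometry/glucose pairing."""

    lags_s: np.ndarray   # seconds; positive = photometry follows glucose
    rho: np.ndarray      # Spearman rho per lag; NaN where undefined

    @property
    def peak_lag_s(self) -> Optional[float]:
        """Lag of the extremal |rho|, or None if every lag is undefined."""
        if np.all(np.isnan(self.rho)):
            return None
        idx = int(np.nanargmax(np.abs(self.rho)))
        return float(self.lags_s[idx])

    @property
    def peak_rho(self) -> Optional[float]:
        if np.all(np.isnan(self.rho)):
            return None
        idx = int(np.nanargmax(np.abs(self.rho)))
        return float(self.rho[idx])


@dataclass
class NullEnsemble:
    """Pseudosession null correlograms for one photometry trace."""

    lags_s: np.ndarray
    rho: np.ndarray          # (n_pairings, n_lags)
    min_offset_s: float

    @property
    def n_pairings(self) -> int:
        return self.rho.shape[0]


@dataclass
class GroupCorrelogram:
    """Cohort-level correlogram with null-referenced per-lag significance."""

    lags_s: np.ndarray
    mean_rho: np.ndarray        # Fisher-z average mapped back to rho
    p_raw: np.ndarray           # NaN outside the tested family
    p_bh: np.ndarray
    significant: np.ndarray     # adjusted p < alpha
    alpha: float
    family_size: int


def _segment_rho(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rho of two equal-length segments; NaN if either is constant."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    ra = _stats.rankdata(a)
    rb = _stats.rankdata(b)
    ra -= ra.mean()
    rb -= rb.mean()
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    if denom == 0:
        return np.nan
    return float((ra @ rb) / denom)


def lagged_spearman(
    fp: UniformTrace,
    bg: UniformTrace,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
    step_s: float = 1.0,
    min_overlap: int = MIN_OVERLAP_SAMPLES,
) -> Correlogram:
    """Spearman correlation of fp against bg over a symmetric grid of lags.

    At lag L > 0 the photometry sample at time t is paired with the glucose
    sample at time t - L (photometry *follows* glucose); the overlap shrinks
    with |L| and lags with fewer than ``min_overlap`` samples are undefined.
    """
    if fp.n != bg.n or fp.t0 != bg.t0 or fp.fs != bg.fs:
        raise ValueError("fp and bg must share the same time axis")
    n = fp.n
    max_lag = int(round(max_lag_s * fp.fs))
    step = max(1, int(round(step_s * fp.fs)))
    lags = np.arange(-max_lag, max_lag + 1, step)
    if n - max_lag < min_overlap:
        # every extreme lag would be undefined; require a sane overlap budget
        if n < min_overlap:
            raise ValueError("series too short for any admissible lag")
    rho = np.full(lags.size, np.nan)
    x = fp.values
    y = bg.values
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = x[lag:], y[: n - lag]
        else:
            a, b = x[: n + lag], y[-lag:]
        if a.size < min_overlap:
            continue
        rho[i] = _segment_rho(a, b)
    return Correlogram(lags_s=lags / fp.fs, rho=rho)


def pseudosession_null(
    fp: UniformTrace,
    other_sessions_bg: Sequence[UniformTrace],
    n_pairings: int = 100,
    min_offset_s: float = DEFAULT_MIN_OFFSET_S,
    rng: Optional[np.random.Generator] = None,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
    step_s: float = 1.0,
) -> NullEnsemble:
    """Null correlograms from circularly shifted other-session glucose traces.

    Each pairing draws one of the other sessions' glucose traces and a
    circular shift uniform on ``[min_offset, duration - min_offset]``
    (seconds), then computes a full correlogram against it.  The photometry
    trace is never paired with its own unshifted glucose.
    """
    if not other_sessions_bg:
        raise ValueError(
            "pseudosession null needs at least one other session; a "
            "within-session circular-shift fallback would be a different null"
        )
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    lags_s = None
    for _ in range(n_pairings):
        bg = other_sessions_bg[int(rng.integers(len(other_sessions_bg)))]
        dur = bg.n
        min_off = int(round(min_offset_s * bg.fs))
        hi = dur - min_off
        if hi < min_off:
            raise ValueError("session too short for the minimum circular offset")
        shift = min_off if hi == min_off else int(rng.integers(min_off, hi + 1))
        shifted = bg.with_values(np.roll(bg.values, shift))
        cg = lagged_spearman(fp, shifted, max_lag_s=max_lag_s, step_s=step_s)
        rows.append(cg.rho)
        lags_s = cg.lags_s
    return NullEnsemble(
        lags_s=lags_s, rho=np.vstack(rows), min_offset_s=min_offset_s
    )


def _fisher_mean(rhos: np.ndarray) -> float:
    clipped = np.clip(rhos, -1 + 1e-6, 1 - 1e-6)
    return float(np.tanh(np.mean(np.arctanh(clipped))))


def group_significance(
    real: Sequence[Correlogram],
    null: Sequence[NullEnsemble],
    alpha: float = 0.01,
) -> GroupCorrelogram:
    """Fisher-z group average with per-lag rank-sum tests against the null.

    At each lag the per-session real correlations are compared with the
    pooled pseudosession null correlations by a two-sided Wilcoxon rank-sum
    (Mann-Whitney) test; p-values are then Benjamini-Hochberg adjusted
    across the family of defined lags.  Lags with undefined rho in every
    session are excluded from the family.
    """
    if len(real) < 3:
        raise ValueError("group summary requires at least 3 sessions")
    lags_s = real[0].lags_s
    for cg in real:
        if not np.array_equal(cg.lags_s, lags_s):
            raise ValueError("correlograms must share a lag grid")
    real_mat = np.vstack([cg.rho for cg in real])        # (sessions, lags)
    null_mat = np.vstack([ne.rho for ne in null])        # (pairings_total, lags)

    n_lags = lags_s.size
    mean_rho = np.full(n_lags, np.nan)
    p_raw = np.full(n_lags, np.nan)
    testable = []
    for j in range(n_lags):
        rv = real_mat[:, j]
        rv = rv[~np.isnan(rv)]
        nv = null_mat[:, j]
        nv = nv[~np.isnan(nv)]
        if rv.size == 0:
            continue
        mean_rho[j] = _fisher_mean(rv)
        if nv.size == 0:
            continue
        res = _stats.mannwhitneyu(rv, nv, alternative="two-sided")
        p_raw[j] = res.pvalue
        testable.append(j)

    p_bh = np.full(n_lags, np.nan)
    significant = np.zeros(n_lags, dtype=bool)
    if testable:
        idx = np.array(testable)
        rej, adj, *_ = multipletests(p_raw[idx], alpha=alpha, method="fdr_bh")
        p_bh[idx] = adj
        significant[idx] = adj < alpha
    return GroupCorrelogram(
        lags_s=lags_s,
        mean_rho=mean_rho,
        p_raw=p_raw,
        p_bh=p_bh,
        significant=significant,
        alpha=alpha,
        family_size=len(testable),
    )


def peak_lag_compare(
    peaks_a: dict[str, float],
    peaks_b: dict[str, float],
) -> dict:
    """Paired comparison of per-session peak lags between two conditions.

    Sessions missing from either condition are excluded pairwise.  Returns
    the matched differences (b - a, seconds) and a two-sided Wilcoxon
    signed-rank test (delegated to :mod:`glycofp.stats`).
    """
    from .stats import paired_timing_test

    shared = sorted(set(peaks_a) & set(peaks_b))
    if len(shared) < 2:
        raise ValueError("paired peak-lag comparison needs >= 2 matched sessions")
    a = np.array([peaks_a[s] for s in shared])
    b = np.array([peaks_b[s] for s in shared])
    stat, p = paired_timing_test(a, b)
    return {
        "session_ids": shared,
        "diff_s": b - a,
        "median_diff_s": float(np.median(b - a)),
        "statistic": stat,
        "p_value": p,
    }
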