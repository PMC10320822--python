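"""Group comparisons, index-performance correlations, trial-level models,
and difficulty-adaptation analyses.

The analysis ladder mirrors standard practice in strategy-use studies:

1. Univariate outlier trimming (> 2.5 SD from the group mean, single pass,
   applied per index and per analysis).
2. Welch two-sample comparisons between groups plus a Levene/Brown-Forsythe
   variance-homogeneity check, optionally adjusted for a data-quality
   covariate.
3. Pearson correlations between participant-level strategy indices and
   percent correct (with t statistics and 95% CIs).
4. Trial-level logistic mixed models: accuracy ~ index + difficulty +
   (1 | participant), one model per index.
5. Item-level adaptation: group-mean index per item regressed on item
   difficulty.
6. Participant-level adaptation: index ~ difficulty + (difficulty |
   participant); the conditional (posterior-mean) participant slopes are
   the per-person adaptation indices, which are then correlated with
   overall performance.

No multiple-comparison correction is applied by default (an FDR helper is
available but off by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .glmm import fit_logistic_mixed

__all__ = [
    "CorrelationResult",
    "remove_outliers",
    "compare_groups",
    "pearson_with_ci",
    "correlate_index_performance",
    "trial_level_model",
    "item_level_adaptation",
    "adaptation_slopes",
    "correlate_adaptation_performance",
]

DEFAULT_INDICES = [
    "pct_encoding",
    "pct_integration",
    "n_toggles",
    "toggle_rate",
    "time_to_first_toggle",
    "prop_matrix_time",
    "matrix_time_distribution",
]

TRIAL_INDICES = [
    "encoding",
    "integration",
    "toggle_rate",
    "time_to_first_toggle",
    "prop_matrix_time",
    "matrix_time_distribution",
]

BINARY_INDICES = {"encoding", "integration"}


@dataclass(frozen=True)
class CorrelationResult:
    index: str
    group: object
    r: float
    ci_lo: float
    ci_hi: float
    t: float
    p: float
    n: int


def remove_outliers(values, k: float = 2.5) -> np.ndarray:
    """Boolean mask of retained values: |v - mean| <= k * SD, with mean and
    SD taken from the full set in a single pass.  Zero SD removes nothing."""
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("need at least 3 values for outlier trimming")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.ones(v.size, bool)
    return np.abs(v - v.mean()) <= k * sd


def compare_groups(
    a,
    b,
    *,
    welch: bool = True,
    levene_center: str = "median",
    covariate_a=None,
    covariate_b=None,
) -> dict:
    """Two-sample comparison of one participant-level index.

    Returns the (Welch by default) t statistic with df and p, a Levene /
    Brown-Forsythe variance-homogeneity test, and -- when per-participant
    covariate values are supplied (e.g. fraction of available eyetracking
    data) -- the group coefficient from an ANCOVA-style OLS adjustment.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    tt = sps.ttest_ind(a, b, equal_var=not welch)
    lv = sps.levene(a, b, center=levene_center)
    out = {
        "t": float(tt.statistic),
        "df": float(tt.df),
        "p": float(tt.pvalue),
        "levene_F": float(lv.statistic),
        "levene_p": float(lv.pvalue),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
    if covariate_a is not None and covariate_b is not None:
        yv = np.r_[a, b]
        gdum = np.r_[np.zeros(a.size), np.ones(b.size)]
        cov = np.r_[np.asarray(covariate_a, float), np.asarray(covariate_b, float)]
        Xd = sm.add_constant(np.column_stack([gdum, cov]))
        fit = sm.OLS(yv, Xd).fit()
        out["adjusted_t"] = float(fit.tvalues[1])
        out["adjusted_p"] = float(fit.pvalues[1])
    return out


def pearson_with_ci(x, y, *, index: str = "", group=None) -> CorrelationResult:
    """Pearson r with the t statistic ``r * sqrt((n-2)/(1-r^2))`` and a
    Fisher-z 95% CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) < 1.0:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    else:
        t = np.inf * np.sign(r)
    if n >= 4:
        ci = res.confidence_interval()
        lo, hi = float(ci.low), float(ci.high)
    else:
        lo = hi = np.nan
    return CorrelationResult(
        index=index, group=group, r=r, ci_lo=lo, ci_hi=hi,
        t=float(t), p=float(res.pvalue), n=n,
    )


def _trimmed_pairs(x, y, trim_sd):
    if trim_sd is None:
        return x, y
    keep = remove_outliers(x, trim_sd) & remove_outliers(y, trim_sd)
    return x[keep], y[keep]


def correlate_index_performance(
    participants: pd.DataFrame,
    *,
    indices: list[str] | None = None,
    group_col: str = "group",
    perf_col: str = "percent_correct",
    trim_sd: float | None = 2.5,
    exclude_below_chance: float | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Pearson correlations between each strategy index and performance,
    per group, with per-analysis outlier trimming.

    ``exclude_below_chance`` (a percent, e.g. 12.5) re-runs the analysis
    with participants at or below that accuracy removed -- the sensitivity
    variant guarding against participants who did not understand the task.
    """
    if indices is None:
        indices = [c for c in DEFAULT_INDICES if c in participants.columns]
    df = participants
    if exclude_below_chance is not None:
        df = df[df[perf_col] >= exclude_below_chance]
    rows = []
    for grp, g in df.groupby(group_col):
        for idx in indices:
            x = g[idx].to_numpy(float)
            y = g[perf_col].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = _trimmed_pairs(x[ok], y[ok], trim_sd)
            rows.append(pearson_with_ci(x, y, index=idx, group=grp).__dict__)
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def trial_level_model(
    trials: pd.DataFrame,
    index: str,
    *,
    outcome: str = "correct",
    difficulty_col: str = "difficulty",
    n_quad: int = 15,
) -> pd.DataFrame:
    """Logistic mixed model ``accuracy ~ index + difficulty +
    (1 | participant)`` for one strategy index.

    Returns the fixed-effect summary (B, 95% CI, z, p) plus the
    random-intercept SD and a convergence flag; raises if the index has no
    variance (unidentifiable model).
    """
    df = trials.dropna(subset=[index, outcome, difficulty_col])
    xv = df[index].to_numpy(float)
    if np.ptp(xv) == 0:
        raise ValueError(f"index {index!r} has zero variance: model unidentifiable")
    X = np.column_stack(
        [np.ones(len(df)), xv, df[difficulty_col].to_numpy(float)]
    )
    res = fit_logistic_mixed(
        df[outcome].to_numpy(float),
        X,
        df["participant"].to_numpy(),
        names=["intercept", index, difficulty_col],
        n_quad=n_quad,
    )
    if not res.converged:
        warnings.warn(f"trial-level model for {index!r} did not converge")
    out = res.summary_frame()
    out["re_intercept_sd"] = res.re_sd["intercept"]
    out["converged"] = res.converged
    out["n_obs"] = res.n_obs
    out["n_participants"] = res.n_groups
    return out


def item_level_adaptation(
    trials: pd.DataFrame,
    *,
    indices: list[str] | None = None,
    difficulty_col: str = "difficulty",
    group_col: str | None = None,
) -> pd.DataFrame:
    """Item-level strategy shift with difficulty.

    Each index is averaged within item (per group when ``group_col`` is
    given); the item means are then correlated with item difficulty, n =
    number of items.  ``n_toggles`` is included here because an increase in
    raw toggles with difficulty marks a shift toward (hybrid) response
    elimination even when toggle *rate* falls with longer solving times.
    """
    if indices is None:
        indices = [c for c in TRIAL_INDICES + ["n_toggles"] if c in trials.columns]
    keys = ([group_col] if group_col else []) + ["trial"]
    rows = []
    grouped = trials.groupby(keys)[indices + [difficulty_col]].mean().reset_index()
    for grp, g in (
        grouped.groupby(group_col) if group_col else [(None, grouped)]
    ):
        d = g[difficulty_col].to_numpy(float)
        if np.ptp(d[np.isfinite(d)]) == 0:
            raise ValueError("difficulty is constant across items")
        for idx in indices:
            x = g[idx].to_numpy(float)
            if np.ptp(x[np.isfinite(x)]) == 0:
                rows.append(
                    CorrelationResult(idx, grp, 0.0, np.nan, np.nan, 0.0, 1.0,
                                      int(np.isfinite(x).sum())).__dict__
                )
                continue
            rows.append(pearson_with_ci(d, x, index=idx, group=grp).__dict__)
    return pd.DataFrame(rows)


def adaptation_slopes(
    trials: pd.DataFrame,
    index: str,
    *,
    difficulty_col: str = "difficulty",
    link: str = "auto",
    n_quad: int = 9,
) -> pd.DataFrame:
    """Per-participant conditional slopes of one index on item difficulty.

    Fits ``index ~ difficulty + (difficulty | participant)`` -- a linear
    mixed model for continuous indices, a logistic one for the binary
    encoding/integration flags (``link='auto'``; force with ``'linear'`` or
    ``'logit'``).  The extracted per-participant slopes (fixed slope +
    conditional mode/mean of the random slope) quantify difficulty
    adaptation; values away from 0 mean stronger adaptation.  If the mixed
    fit fails to converge, per-participant ordinary regressions are used
    and flagged.
    """
    df = trials.dropna(subset=[index, difficulty_col]).copy()
    y = df[index].to_numpy(float)
    d = df[difficulty_col].to_numpy(float)
    pid = df["participant"].to_numpy()
    is_binary = set(np.unique(y)) <= {0.0, 1.0}
    use_logit = link == "logit" or (link == "auto" and is_binary)

    # center and scale to unit SD for optimizer stability; slopes are
    # rescaled back to per-difficulty-percent units afterwards
    d_sd = d.std()
    if d_sd == 0:
        raise ValueError("difficulty is constant: slopes unidentifiable")
    d_c = (d - d.mean()) / d_sd
    if use_logit:
        X = np.column_stack([np.ones(len(df)), d_c])
        res = fit_logistic_mixed(
            y, X, pid, names=["intercept", difficulty_col],
            slope_of=d_c, n_quad=n_quad,
        )
        fixed_slope = float(res.beta[1]) / d_sd
        sl = res.ranef.set_index("group")["slope"] / d_sd
        out = pd.DataFrame(
            {
                "participant": sl.index,
                "slope": fixed_slope + sl.to_numpy(),
                "fixed_slope": fixed_slope,
                "method": "logit_mixed",
                "converged": res.converged,
            }
        )
        if res.converged:
            return out.reset_index(drop=True)
    else:
        exog = sm.add_constant(d_c)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.MixedLM(y, exog, groups=pid, exog_re=exog)
                fit = md.fit(reml=True, method="lbfgs", maxiter=200)
            if fit.converged:
                fixed_slope = float(fit.fe_params[1]) / d_sd
                re = fit.random_effects
                rows = [
                    {
                        "participant": g,
                        "slope": fixed_slope + float(np.asarray(eff)[-1]) / d_sd,
                        "fixed_slope": fixed_slope,
                        "method": "linear_mixed",
                        "converged": True,
                    }
                    for g, eff in re.items()
                ]
                return pd.DataFrame(rows)
        except (np.linalg.LinAlgError, ValueError):
            pass

    # fallback: per-participant ordinary regressions, flagged
    warnings.warn(
        f"mixed model for {index!r} did not converge; "
        "falling back to per-participant OLS slopes"
    )
    rows = []
    for g, gd in df.groupby("participant"):
        dd = gd[difficulty_col].to_numpy(float)
        yy = gd[index].to_numpy(float)
        if np.ptp(dd) == 0 or len(dd) < 3:
            slope = np.nan
        else:
            slope = float(np.polyfit(dd, yy, 1)[0])
        rows.append(
            {
                "participant": g,
                "slope": slope,
                "fixed_slope": np.nan,
                "method": "per_participant_ols",
                "converged": False,
            }
        )
    return pd.DataFrame(rows)


def correlate_adaptation_performance(
    slopes: pd.DataFrame,
    participants: pd.DataFrame,
    *,
    perf_col: str = "percent_correct",
    group_col: str | None = "group",
    index: str = "",
    trim_sd: float | None = 2.5,
) -> pd.DataFrame:
    """Pearson correlations between extracted adaptation slopes and overall
    performance, per group, with outlier-trimmed slopes."""
    merged = slopes.merge(
        participants[
            ["participant", perf_col] + ([group_col] if group_col else [])
        ],
        on="participant",
    )
    rows = []
    for grp, g in (
        merged.groupby(group_col) if group_col else [(None, merged)]
    ):
        x = g["slope"].to_numpy(float)
        y = g[perf_col].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = _trimmed_pairs(x[ok], y[ok], trim_sd)
        rows.append(pearson_with_ci(x, y, index=index, group=grp).__dict__)
    return pd.DataFrame(rows)
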