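"""One-command end-to-end analysis: fixation + response tables in,
Tables 1-5 style outputs out.

``run_pipeline`` chains the full ladder: QC and trial exclusion, trial-level
strategic indices, participant aggregation, descriptives with Cronbach's
alpha per index (Table 1 analogue), index-performance correlations (Table
2), trial-level logistic mixed models (Table 3), item-level difficulty
adaptation (Table 4), and random-slope adaptation indices correlated with
performance (Table 5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import indices as idx_mod
from . import scoring, stats

__all__ = ["PipelineResult", "run_pipeline"]

AGG_INDICES = stats.DEFAULT_INDICES


@dataclass
class PipelineResult:
    trial_indices: pd.DataFrame
    participants: pd.DataFrame
    qc: pd.DataFrame
    item_difficulty: pd.DataFrame
    descriptives: pd.DataFrame  # Table 1 analogue (per group, with alpha)
    index_performance: pd.DataFrame  # Table 2 analogue
    trial_models: pd.DataFrame | None  # Table 3 analogue
    item_adaptation: pd.DataFrame  # Table 4 analogue
    adaptation_slopes: dict  # index -> per-participant slope table
    adaptation_performance: pd.DataFrame  # Table 5 analogue


def _descriptives(parts: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Group descriptives plus reliability (Cronbach's alpha over trials in
    fixed task order) for each index and for accuracy."""
    rows = []
    alpha_cols = {
        "pct_encoding": "encoding",
        "pct_integration": "integration",
        "n_toggles": "n_toggles",
        "toggle_rate": "toggle_rate",
        "time_to_first_toggle": "time_to_first_toggle",
        "prop_matrix_time": "prop_matrix_time",
        "matrix_time_distribution": "matrix_time_distribution",
        "response_time": "response_time",
    }
    for grp, g in parts.groupby("group"):
        gt = trials[trials["participant"].isin(g["participant"])]
        for col in ["percent_correct", "response_time"] + AGG_INDICES:
            if col not in g:
                continue
            v = g[col].to_numpy(float)
            alpha = np.nan
            tcol = alpha_cols.get(col)
            if col == "percent_correct" and "correct" in gt:
                tcol = "correct"
            if tcol and tcol in gt:
                wide = gt.pivot_table(
                    index="participant", columns="trial", values=tcol
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        alpha = idx_mod.cronbach_alpha(wide.to_numpy(float))
                    except ValueError:
                        alpha = np.nan
            rows.append(
                {
                    "group": grp,
                    "variable": col,
                    "mean": float(np.nanmean(v)),
                    "sd": float(np.nanstd(v, ddof=1)),
                    "min": float(np.nanmin(v)),
                    "max": float(np.nanmax(v)),
                    "alpha": alpha,
                    "n": int(np.isfinite(v).sum()),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    fixations: pd.DataFrame,
    responses: pd.DataFrame,
    *,
    group_col: str = "group",
    qc_threshold: float = 0.20,
    trim_sd: float = 2.5,
    fit_trial_models: bool = True,
    adaptation_indices: list[str] | None = None,
    exclude_below_chance: float | None = None,
    n_options: int = 8,
) -> PipelineResult:
    """Run the complete analysis from an AOI-labelled fixation table and a
    response table (``participant, group, trial, correct, trial_duration``).

    Trials whose valid fraction falls below ``qc_threshold`` are excluded
    before any index is aggregated; item difficulty is recomputed per group
    from the retained responses (100 - mean percent correct).
    """
    trial_durations = responses[["participant", "trial", "trial_duration"]]
    trials = idx_mod.trial_table(fixations, trial_durations=trial_durations)

    qc = trials[["participant", "trial", "valid_fraction"]].copy()
    qc["group"] = qc["participant"].map(
        dict(zip(responses["participant"], responses[group_col]))
    )
    from .preprocess import exclude_trials_participants

    qc = exclude_trials_participants(qc, min_valid_fraction=qc_threshold)
    keep = ~qc["excluded"].to_numpy()
    trials = trials.loc[keep].reset_index(drop=True)

    resp = responses.merge(
        trials[["participant", "trial"]], on=["participant", "trial"]
    )
    # behavioural item difficulty per group, attached to each trial
    diff = scoring.item_difficulty(resp, group_col=group_col)
    trials = trials.merge(
        resp[["participant", "trial", group_col, "correct"]],
        on=["participant", "trial"],
    )
    trials = trials.merge(
        diff.rename(columns={"item": "trial"})[["trial", "group", "difficulty"]],
        left_on=["trial", group_col],
        right_on=["trial", "group"],
    )

    parts = idx_mod.aggregate_participants(trials, resp)
    parts = parts.merge(
        resp[["participant", group_col]].drop_duplicates(), on="participant"
    )

    desc = _descriptives(parts, trials)
    tab2 = stats.correlate_index_performance(
        parts, group_col=group_col, trim_sd=trim_sd,
        exclude_below_chance=exclude_below_chance,
    )

    tab3 = None
    if fit_trial_models:
        mrows = []
        for grp, g in trials.groupby(group_col):
            for index in stats.TRIAL_INDICES:
                try:
                    res = trial_level_model_safe(g, index)
                except ValueError:
                    continue
                if res is not None:
                    res.insert(0, "group", grp)
                    res.insert(1, "index", index)
                    mrows.append(res[res["term"] == index])
        tab3 = pd.concat(mrows, ignore_index=True) if mrows else pd.DataFrame()

    tab4 = stats.item_level_adaptation(trials, group_col=group_col)

    if adaptation_indices is None:
        adaptation_indices = ["encoding", "toggle_rate", "time_to_first_toggle"]
    slope_tables = {}
    t5_rows = []
    for index in adaptation_indices:
        per_group = []
        for grp, g in trials.groupby(group_col):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sl = stats.adaptation_slopes(g, index)
            sl.insert(1, "group", grp)
            per_group.append(sl)
        slopes = pd.concat(per_group, ignore_index=True)
        slope_tables[index] = slopes
        t5 = stats.correlate_adaptation_performance(
            slopes.drop(columns=["group"]), parts, index=index, trim_sd=trim_sd
        )
        t5_rows.append(t5)
    tab5 = pd.concat(t5_rows, ignore_index=True) if t5_rows else pd.DataFrame()

    return PipelineResult(
        trial_indices=trials,
        participants=parts,
        qc=qc,
        item_difficulty=diff,
        descriptives=desc,
        index_performance=tab2,
        trial_models=tab3,
        item_adaptation=tab4,
        adaptation_slopes=slope_tables,
        adaptation_performance=tab5,
    )


def trial_level_model_safe(g: pd.DataFrame, index: str) -> pd.DataFrame | None:
    """Trial-level mixed logistic model, or None when it cannot be fit
    (e.g. accuracy constant within the group)."""
    if g["correct"].nunique() < 2:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.trial_level_model(g, index)
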