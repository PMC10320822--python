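"""Response scoring: accuracy, relational score, error types, item difficulty.

Each matrix problem offers ``n_options`` answer options (8 by default), of
which exactly one is correct.  Besides right/wrong accuracy, two further
descriptions of a response are computed:

* the *relational score* -- credit for the number of matrix relations the
  chosen option embodies (an option matching 2 of 3 relations scores 2),
  summed over retained trials; it widens the performance range relative to
  percent correct.
* the *error type* -- incorrect responses are classified as ``duplicate``
  (a copy of a matrix item), ``novel_feature`` (contains a feature absent
  from the matrix), ``partial`` (matches >= 1 but not all relations), or
  ``other``, with that fixed precedence.

Item difficulty is defined behaviourally per group as 100 minus the group's
mean percent correct on the item, so higher numbers mean harder problems.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "percent_correct",
    "relational_score",
    "classify_error",
    "classify_errors",
    "item_difficulty",
    "chance_level",
]

ERROR_TYPES = ("correct", "duplicate", "novel_feature", "partial", "other")


def percent_correct(responses: pd.DataFrame) -> float:
    """Percent correct over one participant's retained trials."""
    if len(responses) == 0:
        raise ValueError("participant has zero retained trials")
    return float(100.0 * responses["correct"].mean())


def relational_score(
    responses: pd.DataFrame,
    options: pd.DataFrame,
    *,
    per_relation_credit: float = 1.0,
) -> float:
    """Sum over retained trials of the chosen option's matched-relation count.

    ``options`` must carry one row per (item, option) with an
    ``n_relations_matched`` column (0..3).  Trials whose chosen option has no
    metadata are skipped with a warning.  ``per_relation_credit`` rescales
    the credit per matched relation (fractional rubrics are possible).
    """
    merged = responses.merge(
        options,
        left_on=["trial", "chosen"],
        right_on=["item", "option"],
        how="left",
    )
    missing = merged["n_relations_matched"].isna()
    if missing.any():
        warnings.warn(f"skipping {int(missing.sum())} trial(s) without option metadata")
    return float(
        (merged.loc[~missing, "n_relations_matched"] * per_relation_credit).sum()
    )


def classify_error(
    correct: bool,
    is_duplicate: bool,
    has_novel_feature: bool,
    n_relations_matched: int,
) -> str:
    """Single error label with fixed precedence
    duplicate > novel_feature > partial > other."""
    if correct:
        return "correct"
    if is_duplicate:
        return "duplicate"
    if has_novel_feature:
        return "novel_feature"
    if n_relations_matched >= 1:
        return "partial"
    return "other"


def classify_errors(responses: pd.DataFrame, options: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_error` for a response table joined against
    per-option feature flags."""
    merged = responses.merge(
        options,
        left_on=["trial", "chosen"],
        right_on=["item", "option"],
        how="left",
        validate="many_to_one",
    )
    out = np.where(
        merged["correct"].to_numpy(bool),
        "correct",
        np.where(
            merged["is_duplicate"].fillna(False).to_numpy(bool),
            "duplicate",
            np.where(
                merged["has_novel_feature"].fillna(False).to_numpy(bool),
                "novel_feature",
                np.where(
                    merged["n_relations_matched"].fillna(0).to_numpy() >= 1,
                    "partial",
                    "other",
                ),
            ),
        ),
    )
    return pd.Series(out, index=responses.index, name="error_type")


def item_difficulty(
    responses: pd.DataFrame, group_col: str = "group"
) -> pd.DataFrame:
    """Per-item, per-group difficulty: 100 - mean percent correct.

    Items with no responses in a group are simply absent from that group's
    rows (warned).  Output columns: ``item, group, mean_pct_correct,
    difficulty, n``.
    """
    g = responses.groupby([group_col, "trial"])
    out = g.agg(mean_pct_correct=("correct", "mean"), n=("correct", "size"))
    out["mean_pct_correct"] *= 100.0
    out["difficulty"] = 100.0 - out["mean_pct_correct"]
    out = out.reset_index().rename(columns={"trial": "item", group_col: "group"})
    n_groups = responses[group_col].nunique()
    n_items = responses["trial"].nunique()
    if len(out) < n_groups * n_items:
        warnings.warn("some items have no responses in some group; excluded")
    return out


def chance_level(n_options: int) -> float:
    """Expected percent correct of a uniform random responder."""
    if n_options < 2:
        raise ValueError("need at least 2 answer options")
    return 100.0 / n_options
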