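"""Trial-level strategic indices from AOI-labelled fixation sequences.

Seven indices summarise how a participant scanned a 3x3 matrix-completion
problem, following the constructive-matching vs response-elimination
literature:

* ``encoding`` -- some window of three *consecutive* fixations covers the
  three distinct cells of one matrix row or column (a row/column sweep),
  anywhere in the trial.  Reflects constructive matching.
* ``integration`` -- both a row sweep and a column sweep occur in the same
  trial.  Implies ``encoding``.
* ``n_toggles`` -- number of gaze transitions between the matrix (cells 1-9)
  and the solution array (AOI 10), in either direction.
* ``toggle_rate`` -- ``n_toggles`` divided by the response time, in 1/s.
  Reflects response elimination.
* ``time_to_first_toggle`` -- detected AOI fixation time accumulated strictly
  before the first fixation on the solution array (censored at the response
  time when the array is never fixated).
* ``prop_matrix_time`` -- matrix fixation time over matrix + array time.
* ``matrix_time_distribution`` -- share of matrix time on cells {1,2,4,5}
  minus the share on cells {3,6,7,8,9}; in [-1, +1], with -1/9 for perfectly
  even looking.

Response time is the total detected fixation time on the ten AOIs, not
wall-clock trial time.  Off-AOI fixations (label 0) break encoding windows
but are transparent for toggle adjacency; both conventions can be flipped
via keyword flags for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aoi import ARRAY_AOI, EARLY_CELLS, LATE_CELLS

__all__ = [
    "TrialIndices",
    "detect_encoding",
    "detect_integration",
    "count_toggles",
    "toggle_rate",
    "time_to_first_toggle",
    "proportion_matrix_time",
    "matrix_time_distribution",
    "compute_trial_indices",
    "trial_table",
    "aggregate_participants",
    "cronbach_alpha",
]

INDEX_COLUMNS = [
    "encoding",
    "integration",
    "n_toggles",
    "toggle_rate",
    "time_to_first_toggle",
    "prop_matrix_time",
    "matrix_time_distribution",
]


@dataclass(frozen=True)
class TrialIndices:
    """The seven strategic indices for one trial, plus bookkeeping."""

    encoding: bool
    integration: bool
    n_toggles: int
    toggle_rate: float
    time_to_first_toggle: float
    prop_matrix_time: float
    matrix_time_distribution: float
    response_time: float
    valid_fraction: float = np.nan
    first_toggle_censored: bool = False


def _as_aoi_array(aoi_seq) -> np.ndarray:
    a = np.asarray(
        [0 if v is None else int(v) for v in aoi_seq]
        if not isinstance(aoi_seq, np.ndarray)
        else aoi_seq,
        dtype=np.int64,
    )
    if a.size and (a.min() < 0 or a.max() > 10):
        raise ValueError("AOI labels must be in 0..10 (0/None = off-AOI)")
    return a


def detect_encoding(aoi_seq, order_strict: bool = False) -> tuple[bool, bool]:
    """Return ``(row_event, col_event)`` for a fixation-order AOI sequence.

    A row (column) event is a window of three consecutive fixations covering
    the three distinct cells of one row (column).  By default any visiting
    order within the window counts; with ``order_strict`` the window must
    run left-to-right (top-to-bottom).  Off-AOI and solution-array fixations
    break windows.
    """
    a = _as_aoi_array(aoi_seq)
    if a.size < 3:
        return False, False
    w0, w1, w2 = a[:-2], a[1:-1], a[2:]
    cells = (w0 >= 1) & (w0 <= 9) & (w1 >= 1) & (w1 <= 9) & (w2 >= 1) & (w2 <= 9)
    distinct = (w0 != w1) & (w0 != w2) & (w1 != w2)
    ok = cells & distinct
    # row index (a-1)//3 equal across three distinct cells <=> covers that row
    row_ok = ok & ((w0 - 1) // 3 == (w1 - 1) // 3) & ((w0 - 1) // 3 == (w2 - 1) // 3)
    col_ok = ok & ((w0 - 1) % 3 == (w1 - 1) % 3) & ((w0 - 1) % 3 == (w2 - 1) % 3)
    if order_strict:
        inc = (w0 < w1) & (w1 < w2)
        row_ok &= inc
        col_ok &= inc
    return bool(row_ok.any()), bool(col_ok.any())


def detect_integration(aoi_seq, order_strict: bool = False) -> bool:
    """True iff the trial contains both a row and a column sweep."""
    row, col = detect_encoding(aoi_seq, order_strict=order_strict)
    return row and col


def count_toggles(
    aoi_seq,
    skip_off_aoi: bool = True,
    collapse_repeats: bool = True,
) -> int:
    """Number of matrix <-> solution-array transitions.

    Off-AOI fixations are transparent by default (a blink between a matrix
    cell and the array still counts as one toggle); repeated consecutive
    fixations on the same AOI are collapsed before counting so that
    re-fixations within a region never create transitions.
    """
    a = _as_aoi_array(aoi_seq)
    if skip_off_aoi:
        a = a[a > 0]
    else:
        # an off-AOI fixation severs adjacency: count within contiguous runs
        if (a == 0).any():
            return sum(
                count_toggles(chunk, skip_off_aoi=True, collapse_repeats=collapse_repeats)
                for chunk in np.split(a, np.flatnonzero(a == 0))
            )
    if a.size < 2:
        return 0
    if collapse_repeats:
        keep = np.empty(a.size, bool)
        keep[0] = True
        np.not_equal(a[1:], a[:-1], out=keep[1:])
        a = a[keep]
    side = a == ARRAY_AOI
    return int(np.count_nonzero(side[1:] != side[:-1]))


def toggle_rate(n_toggles: int, response_time: float) -> float:
    """Toggles per second of detected AOI fixation time; NaN if that time
    is zero (the trial is then dropped upstream with a warning)."""
    if response_time <= 0:
        warnings.warn("zero response time: toggle rate undefined", stacklevel=2)
        return float("nan")
    return n_toggles / response_time


def time_to_first_toggle(aoi_seq, durations) -> tuple[float, bool]:
    """AOI fixation time accumulated strictly before the first fixation on
    the solution array.

    Returns ``(time, censored)``; when no array fixation occurs the value is
    the full response time and ``censored`` is True.
    """
    a = _as_aoi_array(aoi_seq)
    d = np.asarray(durations, dtype=float)
    on_aoi = a > 0
    hits = np.flatnonzero(a == ARRAY_AOI)
    if hits.size == 0:
        return float(d[on_aoi].sum()), True
    k = hits[0]
    return float(d[:k][on_aoi[:k]].sum()), False


def proportion_matrix_time(aoi_seq, durations) -> float:
    """Matrix fixation time / (matrix + solution-array fixation time)."""
    a = _as_aoi_array(aoi_seq)
    d = np.asarray(durations, dtype=float)
    t_mat = d[(a >= 1) & (a <= 9)].sum()
    t_arr = d[a == ARRAY_AOI].sum()
    if t_mat + t_arr <= 0:
        warnings.warn("no AOI fixation time: proportion undefined", stacklevel=2)
        return float("nan")
    return float(t_mat / (t_mat + t_arr))


def matrix_time_distribution(aoi_seq, durations) -> float:
    """Share of matrix time on cells {1,2,4,5} minus share on {3,6,7,8,9}."""
    a = _as_aoi_array(aoi_seq)
    d = np.asarray(durations, dtype=float)
    t_early = d[np.isin(a, EARLY_CELLS)].sum()
    t_late = d[np.isin(a, LATE_CELLS)].sum()
    t_mat = t_early + t_late
    if t_mat <= 0:
        warnings.warn("no matrix fixation time: distribution undefined", stacklevel=2)
        return float("nan")
    return float((t_early - t_late) / t_mat)


_EARLY_MASK = np.zeros(11, bool)
_EARLY_MASK[list(EARLY_CELLS)] = True
_LATE_MASK = np.zeros(11, bool)
_LATE_MASK[list(LATE_CELLS)] = True


def compute_trial_indices(
    aoi_seq,
    durations,
    *,
    trial_duration: float | None = None,
    order_strict: bool = False,
    toggles_skip_off_aoi: bool = True,
) -> TrialIndices:
    """All seven indices for one trial's AOI-labelled fixation sequence."""
    a = _as_aoi_array(aoi_seq)
    d = np.asarray(durations, dtype=float)
    if a.shape != d.shape:
        raise ValueError("aoi_seq and durations must have the same length")
    on = a > 0
    rt = float(d[on].sum())
    row, col = detect_encoding(a, order_strict=order_strict)
    n_tog = count_toggles(a, skip_off_aoi=toggles_skip_off_aoi)
    # time to first solution-array fixation (censored if it never happens)
    hits = np.flatnonzero(a == ARRAY_AOI)
    if hits.size:
        k = int(hits[0])
        ttft, censored = float(d[:k][on[:k]].sum()), False
    else:
        ttft, censored = rt, True
    t_early = float(d[_EARLY_MASK[a]].sum())
    t_late = float(d[_LATE_MASK[a]].sum())
    t_mat = t_early + t_late
    t_arr = rt - t_mat
    rate = n_tog / rt if rt > 0 else float("nan")
    pm = t_mat / (t_mat + t_arr) if t_mat + t_arr > 0 else float("nan")
    mtd = (t_early - t_late) / t_mat if t_mat > 0 else float("nan")
    vf = rt / trial_duration if trial_duration and trial_duration > 0 else np.nan
    return TrialIndices(
        encoding=row or col,
        integration=row and col,
        n_toggles=n_tog,
        toggle_rate=rate,
        time_to_first_toggle=ttft,
        prop_matrix_time=pm,
        matrix_time_distribution=mtd,
        response_time=rt,
        valid_fraction=float(vf),
        first_toggle_censored=censored,
    )


def trial_table(
    fixations: pd.DataFrame,
    *,
    trial_durations: pd.DataFrame | None = None,
    order_strict: bool = False,
    toggles_skip_off_aoi: bool = True,
) -> pd.DataFrame:
    """Per-trial index table from a long fixation table.

    ``fixations`` needs columns ``participant, trial, onset, duration, aoi``
    (0 = off-AOI).  ``trial_durations`` optionally supplies wall-clock trial
    time (columns ``participant, trial, trial_duration``) for the
    valid-fraction column.  Trials with zero detected AOI time are dropped
    with a warning.
    """
    fix = fixations.sort_values(["participant", "trial", "onset"])
    dur_map = {}
    if trial_durations is not None:
        dur_map = {
            (r.participant, r.trial): r.trial_duration
            for r in trial_durations.itertuples()
        }
    rows = []
    dropped = 0
    for (p, tr), g in fix.groupby(["participant", "trial"], sort=False):
        ti = compute_trial_indices(
            g["aoi"].to_numpy(),
            g["duration"].to_numpy(),
            trial_duration=dur_map.get((p, tr)),
            order_strict=order_strict,
            toggles_skip_off_aoi=toggles_skip_off_aoi,
        )
        if ti.response_time <= 0:
            dropped += 1
            continue
        rows.append({"participant": p, "trial": tr, **ti.__dict__})
    if dropped:
        warnings.warn(f"dropped {dropped} trial(s) with zero detected AOI time")
    return pd.DataFrame(rows)


def aggregate_participants(
    trials: pd.DataFrame, responses: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Participant-level summary: percent of retained trials with encoding /
    integration, means of the remaining indices, and percent correct when a
    response table (``participant, trial, correct``) is given."""
    if trials.empty:
        raise ValueError("no retained trials to aggregate")
    g = trials.groupby("participant")
    out = pd.DataFrame(
        {
            "n_trials": g.size(),
            "pct_encoding": g["encoding"].mean() * 100.0,
            "pct_integration": g["integration"].mean() * 100.0,
            "n_toggles": g["n_toggles"].mean(),
            "toggle_rate": g["toggle_rate"].mean(),
            "time_to_first_toggle": g["time_to_first_toggle"].mean(),
            "prop_matrix_time": g["prop_matrix_time"].mean(),
            "matrix_time_distribution": g["matrix_time_distribution"].mean(),
            "response_time": g["response_time"].mean(),
        }
    )
    if "valid_fraction" in trials:
        out["valid_fraction"] = g["valid_fraction"].mean()
    if responses is not None:
        merged = trials[["participant", "trial"]].merge(
            responses, on=["participant", "trial"], how="left"
        )
        pc = merged.groupby("participant")["correct"].mean() * 100.0
        out["percent_correct"] = pc
    return out.reset_index()


def cronbach_alpha(trial_by_participant: np.ndarray | pd.DataFrame) -> float:
    """Raw Cronbach's alpha treating trials (columns, fixed task order) as
    items and participants as rows.

    ``alpha = k/(k-1) * (1 - sum of item variances / variance of row sums)``.
    Rows with any missing trial are removed (listwise).  Requires >= 2
    participants and >= 2 items with nonzero total variance; returns NaN when
    the total variance is zero.
    """
    x = np.asarray(trial_by_participant, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 participants and >= 2 trials")
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_var / total_var))
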