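"""Synthetic gaze cohorts for matrix-completion strategy analysis.

Generates simulated participants whose AOI fixation sequences, responses and
difficulty-dependent strategy shifts carry the statistical structure the
analysis pipeline assumes, so every downstream stage can be exercised and
validated without human data.

Generative model (semi-Markov over AOIs, per trial)
---------------------------------------------------
A trial is laid out on the *detected AOI fixation time* clock (which is what
"response time" means throughout this package) as alternating matrix /
solution-array phases:

* total AOI time ``S`` is lognormal around the participant's typical solving
  time, inflated on harder items;
* the first matrix phase lasts ``t1`` (lognormal around the participant's
  ``first_toggle_mean``) -- by construction the measured time to first
  toggle equals ``t1`` exactly;
* the number of matrix<->array transitions is ``1 + Poisson(max(0,
  lambda*S - 1))`` with ``lambda`` the participant's toggle intensity, so
  the expected measured toggle rate equals ``lambda``;
* each phase is filled with lognormal fixation durations floored at 100 ms
  that sum exactly to the phase duration;
* within matrix phases the gaze wanders as a sticky Markov chain over the
  nine cells (repeats and local moves dominate, as in real scanpaths); with
  probability ``p_scan`` a full row sweep (three consecutive fixations
  covering one row) is planted, and independently a column sweep;
* difficulty shifts the strategy: ``logit(p_scan)`` moves by
  ``adapt_scan_slope`` and ``log(lambda)`` by ``adapt_toggle_slope`` per
  difficulty percent;
* off-AOI time (track loss, saccades, looks outside the problem) is added as
  gaps between fixations so that the per-trial valid fraction is
  ``1 - missing``.

The response is drawn from a logistic accuracy model on the *realized* trial
indices: probability correct increases with encoding/integration and a later
first toggle, decreases with toggle rate and difficulty -- the simulation's
ground truth is that constructive matching causes good performance.  When
the correct option is not produced, the error mass is split between
duplicate / novel-feature / partial options, with the duplicate weight
growing with toggle rate (frequent answer-consulters drift toward
perceptual matches).

Every draw flows from one master seed; identical config + seed give
identical cohorts.  A truth table records each participant's drawn
parameters and each trial's latent events for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .aoi import AOILayout, default_layout
from .indices import TrialIndices, compute_trial_indices

__all__ = [
    "StrategyParams",
    "StrategySpread",
    "GroupSpec",
    "AccuracyModel",
    "SimTrialSpec",
    "SimConfig",
    "CohortData",
    "generate_item_bank",
    "simulate_trial",
    "accuracy_model",
    "simulate_cohort",
    "samples_from_fixations",
    "default_config",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class StrategyParams:
    """Generative strategy parameters for one participant (or group means).

    All times in seconds, difficulty in percent units (0-100).
    """

    p_scan: float  # P(plant a row sweep) = P(plant a column sweep), per trial
    toggle_intensity: float  # expected toggles per second of AOI time (1/s)
    first_toggle_mean: float  # mean latency to first solution-array fixation
    fixation_dur_mean: float = 0.25  # arithmetic mean of lognormal durations
    fixation_dur_sd: float = 0.10  # arithmetic SD of lognormal durations
    adapt_scan_slope: float = 0.0  # d logit(p_scan) / d difficulty
    adapt_toggle_slope: float = 0.0  # d log(toggle_intensity) / d difficulty
    missing_frac: float = 0.0  # expected off-AOI fraction of trial time
    trial_time_mean: float = 8.0  # typical AOI time per trial
    trial_time_sd: float = 0.35  # log-scale trial-to-trial SD of AOI time
    rt_difficulty_slope: float = 0.008  # d log(times) / d difficulty
    first_toggle_sd: float = 0.45  # log-scale SD of the first-toggle latency
    early_cell_weight: float = 1.0  # wandering weight of cells {1,2,4,5}
    stay_prob: float = 0.55  # P(re-fixate the same cell) while wandering
    array_dwell_weight: float = 0.7  # rel. expected length of array phases
    #: per-participant shift of the accuracy-model intercept (logit units);
    #: drawn in cohorts from the adaptation propensities (see StrategySpread)
    accuracy_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_scan <= 1.0:
            raise ValueError("p_scan must be in [0, 1]")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must be in [0, 1)")
        for name in (
            "toggle_intensity",
            "first_toggle_mean",
            "fixation_dur_mean",
            "fixation_dur_sd",
            "trial_time_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.stay_prob < 1.0:
            raise ValueError("stay_prob must be in [0, 1)")
        if self.early_cell_weight <= 0:
            raise ValueError("early_cell_weight must be positive")


@dataclass(frozen=True)
class StrategySpread:
    """Between-participant SDs, on the transformed scales."""

    logit_p_scan: float = 1.0
    log_toggle: float = 0.25
    log_first_toggle: float = 0.50
    log_trial_time: float = 0.30
    adapt_scan_slope: float = 0.045
    adapt_toggle_slope: float = 0.012
    missing_conc: float = 80.0  # beta concentration of per-participant missing
    #: correlation between a participant's baseline strategy level and their
    #: difficulty-adaptation slope (adaptive scanners are stronger scanners
    #: overall; adaptive togglers are heavier togglers overall) -- this is
    #: what couples strategy adaptation to overall performance
    scan_adapt_cor: float = 0.9
    toggle_adapt_cor: float = 0.9
    #: direct link from adaptation propensity to the accuracy intercept
    #: (logit units per SD of the slope deviation): individuals who adapt
    #: scanning to difficulty solve more items; individuals who ramp up
    #: toggling on hard items solve fewer
    ability_scan: float = 0.70
    ability_toggle: float = 0.55


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int
    params: StrategyParams  # group means
    spread: StrategySpread = StrategySpread()
    accuracy_intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")


@dataclass(frozen=True)
class AccuracyModel:
    """Logistic model from realized trial indices to response choice.

    ``P(correct) = expit(intercept + ...)``; the coefficients encode the
    causal ground truth of the simulation (constructive matching helps,
    response elimination and difficulty hurt).  Reference values center the
    continuous indices so that group intercepts are interpretable.
    """

    b_encoding: float = 2.2
    b_integration: float = 0.4
    b_toggle_rate: float = -5.5  # per 1/s
    b_first_toggle: float = 0.50  # per second
    b_prop_matrix: float = 1.2
    b_difficulty: float = -0.10  # per difficulty percent (centered)
    #: encoding x difficulty interaction: scanning rows/columns pays off more
    #: on harder, multi-relation items (easy items yield to pattern
    #: completion), which is what makes *adaptive* scanning beneficial
    b_encoding_difficulty: float = 0.03
    tr_ref: float = 0.40
    ttft_ref: float = 3.5
    pm_ref: float = 0.70
    w_duplicate: float = 1.0
    w_novel: float = 1.0
    w_partial: float = 1.0
    w_other: float = 1.0
    duplicate_toggle_coef: float = 2.0  # log duplicate weight per toggle-rate unit
    uniform_guess: bool = False  # ignore the model; choose uniformly


@dataclass(frozen=True)
class SimTrialSpec:
    """Design of one matrix item: difficulty, relations, answer options."""

    item_id: int
    n_relations: int
    difficulty: float  # anticipated difficulty, percent units
    n_options: int
    correct_option: int
    is_duplicate: tuple[bool, ...]
    has_novel_feature: tuple[bool, ...]
    n_relations_matched: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.n_relations <= 3:
            raise ValueError("n_relations must be 1..3")
        if not 0.0 <= self.difficulty <= 100.0:
            raise ValueError("difficulty must be in [0, 100]")
        if len(self.is_duplicate) != self.n_options:
            raise ValueError("option feature length mismatch")
        if self.n_relations_matched[self.correct_option] != self.n_relations:
            raise ValueError("correct option must match all relations")


@dataclass(frozen=True)
class SimConfig:
    groups: tuple[GroupSpec, ...]
    accuracy: AccuracyModel = AccuracyModel()
    n_options: int = 8
    rate: float = 50.0  # Hz, for raw-sample emission
    d_ref: float = 45.0  # difficulty value at which adaptation slopes pivot
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("need at least one group")
        if self.n_options < 4:
            raise ValueError("need >= 4 options (correct + duplicate + novel + 1)")


# ---------------------------------------------------------------------------
# item bank
# ---------------------------------------------------------------------------
#: per-set relation counts: three 1-relation, three 2-relation, two 3-relation
#: items per set of eight (the final item of the task, a logical rule, is
#: treated as a 3-relation stand-in)
_SET_RELATIONS = (1, 1, 1, 2, 2, 2, 3, 3)
_SET_BASES = (25.0, 45.0, 65.0)
_WITHIN_SET_JITTER = (-3.0, 0.0, 3.0, -3.0, 0.0, 3.0, -2.0, 2.0)


def generate_item_bank(config: SimConfig) -> list[SimTrialSpec]:
    """24 items in three sets of eight with increasing anticipated
    difficulty; relation counts follow the 3/3/2 per-set pattern."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7]))
    items: list[SimTrialSpec] = []
    for s, base in enumerate(_SET_BASES):
        for k, (rel, jit) in enumerate(zip(_SET_RELATIONS, _WITHIN_SET_JITTER)):
            item_id = 8 * s + k
            diff = float(np.clip(base + 7.0 * (rel - 2) + jit, 1.0, 99.0))
            n_opt = config.n_options
            correct = int(rng.integers(n_opt))
            others = [o for o in range(n_opt) if o != correct]
            rng.shuffle(others)
            dup, novel = others[0], others[1]
            is_dup = [False] * n_opt
            has_novel = [False] * n_opt
            matched = [0] * n_opt
            is_dup[dup] = True
            has_novel[novel] = True
            matched[correct] = rel
            # remaining incorrect options cycle 0..rel-1 matched relations,
            # so partial and plain-wrong ("other") responses both exist
            for j, o in enumerate(others[2:]):
                matched[o] = j % rel
            items.append(
                SimTrialSpec(
                    item_id=item_id,
                    n_relations=rel,
                    difficulty=diff,
                    n_options=n_opt,
                    correct_option=correct,
                    is_duplicate=tuple(is_dup),
                    has_novel_feature=tuple(has_novel),
                    n_relations_matched=tuple(matched),
                )
            )
    return items


def items_table(items: list[SimTrialSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "item": [it.item_id for it in items],
            "n_relations": [it.n_relations for it in items],
            "design_difficulty": [it.difficulty for it in items],
            "correct_option": [it.correct_option for it in items],
            "n_options": [it.n_options for it in items],
        }
    )


def options_table(items: list[SimTrialSpec]) -> pd.DataFrame:
    rows = []
    for it in items:
        for o in range(it.n_options):
            rows.append(
                {
                    "item": it.item_id,
                    "option": o,
                    "is_correct": o == it.correct_option,
                    "is_duplicate": it.is_duplicate[o],
                    "has_novel_feature": it.has_novel_feature[o],
                    "n_relations_matched": it.n_relations_matched[o],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# single-trial simulation
# ---------------------------------------------------------------------------
def _lognormal_mean(rng, mean: float, log_sd: float, size=None):
    """Lognormal draw(s) with the given *arithmetic* mean."""
    mu = np.log(mean) - 0.5 * log_sd * log_sd
    return rng.lognormal(mu, log_sd, size)


def _fill_durations(rng, total: float, mu_log: float, sd_log: float) -> np.ndarray:
    """Fixation durations >= 0.1 s summing exactly to ``total`` (>= 0.1)."""
    est = int(total / 0.15) + 2
    d = np.maximum(rng.lognormal(mu_log, sd_log, est), 0.1)
    c = np.cumsum(d)
    while c[-1] < total - 0.1:
        d = np.concatenate([d, np.maximum(rng.lognormal(mu_log, sd_log, est), 0.1)])
        c = np.cumsum(d)
    n = int(np.searchsorted(c, total - 0.1, side="right"))
    last = total - (c[n - 1] if n > 0 else 0.0)
    return np.append(d[:n], last)


_ROW_SETS = ((1, 2, 3), (4, 5, 6), (7, 8, 9))
_COL_SETS = ((1, 4, 7), (2, 5, 8), (3, 6, 9))


def simulate_trial(
    params: StrategyParams,
    item: SimTrialSpec,
    seed=None,
    *,
    rng: np.random.Generator | None = None,
    accuracy: AccuracyModel | None = None,
    accuracy_intercept: float = 0.0,
    d_ref: float = 45.0,
    min_first_phase: float = 0.15,
) -> dict:
    """Simulate one trial.

    Returns a dict with the fixation sequence (``aoi``, ``onset``,
    ``duration`` arrays), the wall-clock ``trial_duration``, the realized
    :class:`~matgaze.indices.TrialIndices`, the drawn response (when an
    accuracy model is given) and the latent truth of the trial.  Same seed,
    same output.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    dc = item.difficulty - d_ref
    p_eff = float(expit(logit(min(max(params.p_scan, 1e-9), 1 - 1e-9))
                        + params.adapt_scan_slope * dc))
    if params.p_scan in (0.0, 1.0):
        p_eff = params.p_scan  # degenerate settings stay degenerate
    lam_eff = params.toggle_intensity * np.exp(params.adapt_toggle_slope * dc)
    tscale = np.exp(params.rt_difficulty_slope * dc)

    S = float(_lognormal_mean(rng, params.trial_time_mean * tscale,
                              params.trial_time_sd))
    t1 = float(
        max(_lognormal_mean(rng, params.first_toggle_mean * tscale,
                            params.first_toggle_sd), min_first_phase)
    )
    S = max(S, t1 + 0.6)
    n_tog = 1 + int(rng.poisson(max(lam_eff * S - 1.0, 0.0)))
    n_tog = min(n_tog, max(1, int((S - t1) / 0.13)))

    # alternating phase durations on the AOI-time clock; phase 0 = matrix.
    # Post-first-toggle phases alternate array/matrix; array dwells are
    # shorter on average (answers are glanced at, the matrix is studied).
    rest = S - t1
    g = rng.exponential(size=n_tog)
    g *= np.where(np.arange(1, n_tog + 1) % 2 == 1,
                  params.array_dwell_weight, 1.0)
    g = g / g.sum() * (rest - 0.12 * n_tog) + 0.12
    phase_dur = np.concatenate([[t1], g])

    # fixation durations per phase (sum exactly to the phase duration)
    cv = params.fixation_dur_sd / params.fixation_dur_mean
    sd_log = float(np.sqrt(np.log1p(cv * cv)))
    mu_log = float(np.log(params.fixation_dur_mean) - 0.5 * sd_log * sd_log)
    per_phase = [_fill_durations(rng, pd_, mu_log, sd_log) for pd_ in phase_dur]

    # plant row/column sweeps
    do_row = bool(rng.random() < p_eff)
    do_col = bool(rng.random() < p_eff)
    block: list[int] = []
    if do_row:
        block += list(rng.permutation(_ROW_SETS[rng.integers(3)]))
    if do_col:
        block += list(rng.permutation(_COL_SETS[rng.integers(3)]))
    mat_phase_ids = list(range(0, len(per_phase), 2))
    if block:
        counts = [len(per_phase[i]) for i in mat_phase_ids]
        host = mat_phase_ids[int(np.argmax(counts))]
        need = len(block)
        if len(per_phase[host]) < need:
            tot = max(float(per_phase[host].sum()), 0.1 * need)
            per_phase[host] = np.full(need, tot / need)

    durations = np.concatenate(per_phase)
    n_fix = durations.size
    aoi = np.empty(n_fix, dtype=np.int64)
    is_matrix_fix = np.zeros(n_fix, dtype=bool)
    pos = 0
    phase_start = []
    for i, d in enumerate(per_phase):
        phase_start.append(pos)
        if i % 2 == 0:
            is_matrix_fix[pos:pos + d.size] = True
        else:
            aoi[pos:pos + d.size] = 10
        pos += d.size

    # sticky Markov wandering over the nine cells
    m = int(is_matrix_fix.sum())
    if m:
        we = params.early_cell_weight
        w = np.array([we, we, 1.0, we, we, 1.0, 1.0, 1.0, 1.0])
        w /= w.sum()
        stay = rng.random(m) < params.stay_prob
        stay[0] = False
        targets = rng.choice(9, size=m, p=w)
        jump_idx = np.where(~stay, np.arange(m), 0)
        cells = targets[np.maximum.accumulate(jump_idx)] + 1
        aoi[is_matrix_fix] = cells
    if block:
        nf = len(per_phase[host])
        start = phase_start[host] + int(rng.integers(nf - len(block) + 1))
        aoi[start:start + len(block)] = block

    # off-AOI gaps -> onsets and wall-clock duration
    S_real = float(durations.sum())
    if params.missing_frac > 0:
        conc = 40.0
        miss = float(rng.beta(params.missing_frac * conc,
                              (1.0 - params.missing_frac) * conc))
    else:
        miss = 0.0
    gap_total = S_real * miss / (1.0 - miss)
    gaps = rng.exponential(size=n_fix + 1)
    gaps = gaps / gaps.sum() * gap_total
    onsets = gaps[:-1].cumsum() + (np.cumsum(durations) - durations)
    trial_duration = S_real + gap_total

    idx = compute_trial_indices(aoi, durations, trial_duration=trial_duration)
    out = {
        "aoi": aoi,
        "onset": onsets,
        "duration": durations,
        "trial_duration": trial_duration,
        "indices": idx,
        "latent": {
            "do_row": do_row,
            "do_col": do_col,
            "t1": t1,
            "aoi_time": S_real,
            "n_toggles": n_tog,
            "p_scan_eff": p_eff,
            "toggle_intensity_eff": float(lam_eff),
            "missing": miss,
        },
    }
    if accuracy is not None:
        chosen = accuracy_model(
            accuracy, item, idx, rng=rng,
            intercept=accuracy_intercept, d_ref=d_ref,
        )
        out["chosen"] = chosen
        out["correct"] = chosen == item.correct_option
    return out


def accuracy_model(
    acc: AccuracyModel,
    item: SimTrialSpec,
    realized: TrialIndices,
    *,
    rng: np.random.Generator,
    intercept: float = 0.0,
    d_ref: float = 45.0,
) -> int:
    """Draw a chosen option from the realized trial indices.

    A logistic gate decides whether the correct option is found; otherwise
    the incorrect mass is split among duplicate / novel-feature / partial /
    other options, with the duplicate weight increasing in toggle rate.
    """
    if acc.uniform_guess:
        return int(rng.integers(item.n_options))
    tr = realized.toggle_rate if np.isfinite(realized.toggle_rate) else acc.tr_ref
    pm = (realized.prop_matrix_time
          if np.isfinite(realized.prop_matrix_time) else acc.pm_ref)
    eta = (
        intercept
        + acc.b_encoding * realized.encoding
        + acc.b_integration * realized.integration
        + acc.b_toggle_rate * (tr - acc.tr_ref)
        + acc.b_first_toggle * (realized.time_to_first_toggle - acc.ttft_ref)
        + acc.b_prop_matrix * (pm - acc.pm_ref)
        + acc.b_difficulty * (item.difficulty - d_ref)
        + acc.b_encoding_difficulty * realized.encoding * (item.difficulty - d_ref)
    )
    if rng.random() < expit(eta):
        return item.correct_option
    w = np.empty(item.n_options)
    w_dup = acc.w_duplicate * np.exp(acc.duplicate_toggle_coef * (tr - acc.tr_ref))
    for o in range(item.n_options):
        if o == item.correct_option:
            w[o] = 0.0
        elif item.is_duplicate[o]:
            w[o] = w_dup
        elif item.has_novel_feature[o]:
            w[o] = acc.w_novel
        elif item.n_relations_matched[o] >= 1:
            w[o] = acc.w_partial
        else:
            w[o] = acc.w_other
    tot = w.sum()
    if tot <= 0:
        raise ValueError("error-option weights sum to zero; check AccuracyModel")
    return int(rng.choice(item.n_options, p=w / tot))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------
@dataclass
class CohortData:
    """Everything a simulated study produces, in pipeline-ready tables."""

    fixations: pd.DataFrame  # participant, group, trial, onset, duration, x, y, aoi
    responses: pd.DataFrame  # participant, group, trial, chosen, correct, trial_duration
    items: pd.DataFrame
    options: pd.DataFrame
    truth_participants: pd.DataFrame
    truth_trials: pd.DataFrame
    config: SimConfig
    item_specs: list[SimTrialSpec] = field(repr=False, default_factory=list)
    #: per-trial realized indices, filled when simulating with ``light=True``
    #: (the fixation table is then skipped for speed; the indices are the
    #: same ``compute_trial_indices`` output the pipeline would produce)
    trial_indices: pd.DataFrame | None = None

    def to_dir(self, path) -> None:
        """Write all tables as CSV files under ``path``."""
        import pathlib

        p = pathlib.Path(path)
        p.mkdir(parents=True, exist_ok=True)
        self.fixations.to_csv(p / "fixations.csv", index=False)
        self.responses.to_csv(p / "responses.csv", index=False)
        self.items.to_csv(p / "items.csv", index=False)
        self.options.to_csv(p / "options.csv", index=False)
        self.truth_participants.to_csv(p / "truth_participants.csv", index=False)
        self.truth_trials.to_csv(p / "truth_trials.csv", index=False)


def draw_participant(
    rng: np.random.Generator, grp: GroupSpec
) -> StrategyParams:
    """Draw one participant's parameters around the group means."""
    m, sp = grp.params, grp.spread
    z_scan, z_tog, z_scan2, z_tog2 = rng.standard_normal(4)
    p_scan = m.p_scan
    if 0.0 < p_scan < 1.0 and sp.logit_p_scan > 0:
        p_scan = float(expit(logit(p_scan) + sp.logit_p_scan * z_scan))
    lam = float(m.toggle_intensity
                * np.exp(sp.log_toggle * z_tog
                         - 0.5 * sp.log_toggle ** 2))
    ftm = float(m.first_toggle_mean
                * np.exp(sp.log_first_toggle * rng.standard_normal()
                         - 0.5 * sp.log_first_toggle ** 2))
    tt = float(m.trial_time_mean
               * np.exp(sp.log_trial_time * rng.standard_normal()
                        - 0.5 * sp.log_trial_time ** 2))
    rs, rt_ = sp.scan_adapt_cor, sp.toggle_adapt_cor
    z_a_scan = rs * z_scan + np.sqrt(1 - rs * rs) * z_scan2
    z_a_tog = rt_ * z_tog + np.sqrt(1 - rt_ * rt_) * z_tog2
    a_scan = float(m.adapt_scan_slope + sp.adapt_scan_slope * z_a_scan)
    a_tog = float(m.adapt_toggle_slope + sp.adapt_toggle_slope * z_a_tog)
    acc_off = float(sp.ability_scan * z_a_scan - sp.ability_toggle * z_a_tog)
    miss = m.missing_frac
    if miss > 0 and sp.missing_conc > 0:
        miss = float(rng.beta(miss * sp.missing_conc, (1 - miss) * sp.missing_conc))
        miss = min(miss, 0.95)
    return replace(
        m,
        p_scan=p_scan,
        toggle_intensity=lam,
        first_toggle_mean=ftm,
        trial_time_mean=tt,
        adapt_scan_slope=a_scan,
        adapt_toggle_slope=a_tog,
        missing_frac=miss,
        accuracy_offset=acc_off,
    )


def simulate_cohort(
    config: SimConfig,
    seed: int | None = None,
    *,
    layout: AOILayout | None = None,
    position_jitter: float = 15.0,
    light: bool = False,
) -> CohortData:
    """Simulate every participant of every group over the 24-item bank.

    Fixation centroids are placed at the AOI rectangle centers with Gaussian
    jitter (clipped inside the rectangle) so the tables round-trip through
    AOI assignment.  ``seed`` overrides ``config.seed``.

    With ``light=True`` the fixation table (and centroid placement) is
    skipped and the per-trial realized indices are returned directly in
    ``trial_indices`` -- the choice only affects speed, not the generated
    sequences or responses, which use the same random stream.
    """
    seed = config.seed if seed is None else seed
    if layout is None:
        layout = default_layout()
    items = generate_item_bank(replace(config, seed=seed))
    ss = np.random.SeedSequence(int(seed))
    n_total = sum(g.n for g in config.groups)
    child_seeds = ss.spawn(n_total + 1)

    centers = layout.centers  # (10, 2), row i = AOI i+1
    half_w = np.array([(r[2] - r[0]) / 2 - 2 for _, r in sorted(layout.rects.items())])
    half_h = np.array([(r[3] - r[1]) / 2 - 2 for _, r in sorted(layout.rects.items())])

    fix_parts = []
    resp_rows = []
    truth_p_rows = []
    truth_t_rows = []
    idx_rows = []
    k = 0
    for grp in config.groups:
        for j in range(grp.n):
            pid = f"{grp.label}_{j:03d}"
            # separate streams for behaviour and centroid jitter, so light
            # and full runs generate identical sequences and responses
            s_core, s_pos = child_seeds[k].spawn(2)
            rng = np.random.default_rng(s_core)
            rng_pos = np.random.default_rng(s_pos)
            k += 1
            pp = draw_participant(rng, grp)
            truth_p_rows.append(
                {"participant": pid, "group": grp.label,
                 **{f: getattr(pp, f) for f in (
                     "p_scan", "toggle_intensity", "first_toggle_mean",
                     "trial_time_mean", "adapt_scan_slope",
                     "adapt_toggle_slope", "missing_frac")}}
            )
            for it in items:
                tr = simulate_trial(
                    pp, it, rng=rng,
                    accuracy=config.accuracy,
                    accuracy_intercept=grp.accuracy_intercept + pp.accuracy_offset,
                    d_ref=config.d_ref,
                )
                if light:
                    idx_rows.append(
                        {"participant": pid, "group": grp.label,
                         "trial": it.item_id, **tr["indices"].__dict__}
                    )
                else:
                    a = tr["aoi"]
                    n = a.size
                    jx = rng_pos.standard_normal(n) * position_jitter
                    jy = rng_pos.standard_normal(n) * position_jitter
                    cx = centers[a - 1, 0] + np.clip(jx, -half_w[a - 1], half_w[a - 1])
                    cy = centers[a - 1, 1] + np.clip(jy, -half_h[a - 1], half_h[a - 1])
                    fix_parts.append(
                        (np.full(n, pid, dtype=object), np.full(n, grp.label, object),
                         np.full(n, it.item_id), tr["onset"], tr["duration"], cx, cy, a)
                    )
                resp_rows.append(
                    {
                        "participant": pid,
                        "group": grp.label,
                        "trial": it.item_id,
                        "chosen": tr["chosen"],
                        "correct": bool(tr["correct"]),
                        "trial_duration": tr["trial_duration"],
                    }
                )
                truth_t_rows.append(
                    {"participant": pid, "group": grp.label,
                     "trial": it.item_id, **tr["latent"]}
                )

    cols = ["participant", "group", "trial", "onset", "duration", "x", "y", "aoi"]
    if light:
        fixations = pd.DataFrame(columns=cols)
        trial_idx = pd.DataFrame(idx_rows)
    else:
        fixations = pd.DataFrame(
            {c: np.concatenate([p[i] for p in fix_parts]) for i, c in enumerate(cols)}
        )
        fixations["trial"] = fixations["trial"].astype(np.int64)
        fixations["aoi"] = fixations["aoi"].astype(np.int64)
        trial_idx = None
    return CohortData(
        fixations=fixations,
        trial_indices=trial_idx,
        responses=pd.DataFrame(resp_rows),
        items=items_table(items),
        options=options_table(items),
        truth_participants=pd.DataFrame(truth_p_rows),
        truth_trials=pd.DataFrame(truth_t_rows),
        config=config,
        item_specs=items,
    )


def samples_from_fixations(
    fixations: pd.DataFrame,
    responses: pd.DataFrame,
    *,
    rate: float = 50.0,
    jitter: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Rasterise a fixation table into nominal-rate raw gaze samples.

    Samples inside a fixation get the centroid plus small Gaussian jitter
    and ``valid=1``; samples in the gaps between fixations are emitted as
    track loss (``valid=0``).  Useful for exercising the raw-sample
    preprocessing path end-to-end.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate
    dur_map = {
        (r.participant, r.trial): r.trial_duration for r in responses.itertuples()
    }
    rows = []
    for (p, trial), g in fixations.groupby(["participant", "trial"], sort=False):
        T = dur_map[(p, trial)]
        t = np.arange(0.0, T, dt)
        onset = g["onset"].to_numpy()
        dur = g["duration"].to_numpy()
        idx = np.searchsorted(onset, t, side="right") - 1
        idx = np.clip(idx, 0, len(onset) - 1)
        inside = (t >= onset[idx]) & (t < onset[idx] + dur[idx])
        x = np.where(inside, g["x"].to_numpy()[idx], np.nan)
        y = np.where(inside, g["y"].to_numpy()[idx], np.nan)
        x = x + rng.standard_normal(t.size) * jitter
        y = y + rng.standard_normal(t.size) * jitter
        rows.append(
            pd.DataFrame(
                {
                    "participant": p,
                    "trial": trial,
                    "t": t,
                    "x": x,
                    "y": y,
                    "valid": inside.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------
def default_config(n_per_group: int = 40, seed: int = 0) -> SimConfig:
    """Three groups emulating a developmental matrix-completion study:
    6-year-olds, 9-year-olds and adults, 40 participants each.

    Group means follow the descriptive ranges reported for such cohorts:
    toggle rates falling from ~0.47 to ~0.27 1/s with age, first-toggle
    latencies rising from ~2.2 s to ~8 s, solving times of ~8 s in children
    vs ~22 s in adults, off-AOI fractions of 43% / 31% / 24%, and scanning
    (sweep) propensities increasing with age.  Accuracy intercepts place the
    groups near 34% / 75% / 51% correct on their respective item sets.
    """
    six = GroupSpec(
        label="six",
        n=n_per_group,
        params=StrategyParams(
            p_scan=0.10, toggle_intensity=0.47, first_toggle_mean=2.2,
            adapt_scan_slope=0.030, adapt_toggle_slope=-0.008,
            missing_frac=0.43, trial_time_mean=7.6,
            early_cell_weight=0.50, array_dwell_weight=1.05,
        ),
        accuracy_intercept=-0.84,
    )
    nine = GroupSpec(
        label="nine",
        n=n_per_group,
        params=StrategyParams(
            p_scan=0.32, toggle_intensity=0.38, first_toggle_mean=3.9,
            adapt_scan_slope=0.030, adapt_toggle_slope=-0.003,
            missing_frac=0.31, trial_time_mean=8.9,
            early_cell_weight=0.89, array_dwell_weight=0.70,
        ),
        accuracy_intercept=0.08,
    )
    adults = GroupSpec(
        label="adult",
        n=n_per_group,
        params=StrategyParams(
            p_scan=0.55, toggle_intensity=0.27, first_toggle_mean=8.0,
            adapt_scan_slope=0.025, adapt_toggle_slope=-0.006,
            missing_frac=0.24, trial_time_mean=21.7,
            early_cell_weight=1.33, array_dwell_weight=0.50,
        ),
        accuracy_intercept=-4.60,
    )
    return SimConfig(groups=(six, nine, adults), seed=seed)
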