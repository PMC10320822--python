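# matgaze

Eyetracking strategy analysis for matrix-completion (Raven's-style)
reasoning tasks: from raw gaze samples to the strategic indices that
separate *constructive matching* from *response elimination*, per-group item
difficulty, and statistics of strategy adaptation — plus a synthetic
scanpath simulator that generates complete cohorts with known ground truth.

It is written for researchers who study reasoning strategies with gaze data
(developmental and adult work alike) and for anyone who needs a tested,
fully scriptable reference implementation of the standard AOI-sequence
metrics in this literature.

## The measures

A 3×3 matrix problem is split into ten areas of interest: the matrix cells
1–9 (row-major) and the solution array (AOI 10).  From an AOI-labelled
fixation sequence, per trial:

| index | definition | strategy signature |
|---|---|---|
| encoding | 3 consecutive fixations covering the distinct cells of one row or column | constructive matching |
| integration | both a row and a column sweep in the trial | constructive matching |
| number of toggles *N* | matrix ↔ array gaze transitions | response elimination |
| toggle rate | *N / RT*, with *RT* = total detected AOI fixation time (s⁻¹) | response elimination |
| time to first toggle | AOI fixation time before the first array fixation | constructive matching |
| proportion matrix time | t(matrix) / [t(matrix) + t(array)] | constructive matching |
| matrix time distribution | t{1,2,4,5}/t(matrix) − t{3,6,7,8,9}/t(matrix) ∈ [−1, 1] | completeness of encoding |

Item difficulty is behavioural: `100 − mean % correct` per item and group.
Strategy adaptation is measured by mixed models `index ~ difficulty +
(difficulty | participant)`; the conditional participant slopes are the
adaptation indices, which are then correlated with overall accuracy.
Trial-level specificity uses logistic mixed models `accuracy ~ index +
difficulty + (1 | participant)` (maximum likelihood via Gauss–Hermite
quadrature, implemented in `matgaze.glmm`).

## Worked example

```python
import matgaze as mg

cfg = mg.default_config(n_per_group=40, seed=42)      # 6yo / 9yo / adult-like
cohort = mg.simulate_cohort(cfg, seed=42, light=True)
parts = mg.aggregate_participants(cohort.trial_indices, cohort.responses)
parts = parts.merge(cohort.responses[["participant", "group"]].drop_duplicates())
print(parts.groupby("group")[["percent_correct", "pct_encoding",
                              "toggle_rate", "time_to_first_toggle"]].mean().round(2).T)
```

prints (columns: adult, nine, six):

```
group                 adult   nine    six
percent_correct       55.31  75.83  37.60
pct_encoding          83.33  60.21  35.73
toggle_rate            0.27   0.36   0.52
time_to_first_toggle   8.78   4.74   2.47
```

Reading: the simulated 6-year-old-like group rarely scans full rows or
columns (36% of trials with encoding), consults the answers within ~2.5 s
and toggles twice a second — the response-elimination profile — and scores
near 38% correct; the adult-like group shows the constructive-matching
profile and higher accuracy on its (harder) item set.  `examples/` contains
one narrative script per capability: index computation on a single trial,
raw-sample preprocessing, response scoring, the one-command full analysis
(`mg.run_pipeline`, which emits descriptives with Cronbach's α,
index–performance correlations, trial-level mixed models, item-level
difficulty trends, and adaptation-slope analyses), and adaptation-slope
parameter recovery.

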