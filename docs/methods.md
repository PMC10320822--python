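# Methods

This note documents what `matgaze` computes, the generative model behind
its synthetic cohorts, and the numerical decisions a user should know
before trusting (or changing) a default.

## 1. From gaze samples to fixations

Raw samples `(t, x, y, valid)` at a nominal 50 Hz are classified with a
velocity-threshold (I-VT style) rule.  The threshold is set **per
participant** from that participant's own sample-to-sample velocity
distribution — `median + 3·MAD`, floored at a 30 °/s equivalent
(`px_per_deg = 40` at a typical ~60 cm viewing distance) — so that noisier
recordings (young children) automatically get a higher cut.  The cited
adaptive classifiers in this literature are not specified to the formula;
this robust rule reproduces their intent (correcting for between-group
data-quality differences) and is fully testable.

Conventions:

* a fixation is a run of sub-threshold valid samples of duration
  `n_samples / rate ≥ 100 ms`; shorter runs are discarded;
* invalid gaps `< 75 ms` inside an otherwise stationary run are bridged
  (single dropped samples are common at 50 Hz); bridged samples count
  toward duration but not the centroid;
* saccade samples are excluded from every downstream time sum;
* fixations after the response (the matrix offset) are dropped, and a
  straddling fixation is truncated at the boundary;
* coordinates are screen pixels, origin top-left, y down; AOI rectangles
  are half-open `[x0,x1)×[y0,y1)`, so shared edges cannot double-assign.
  With a positive margin, a point inside several expanded rectangles goes
  to the nearest center (deterministic tie-break).

Data quality per trial is the **valid fraction**: summed AOI-labelled
fixation time over wall-clock trial time (saccades, track loss and off-AOI
looking are all non-valid).  Trials below a configurable threshold
(default 0.20 — published exclusion counts rarely state their criterion)
are excluded, then participants left with no trials.

## 2. Strategic indices

Definitions as in the README.  Decisions that were genuinely open:

* **Window order.** An encoding window is three *consecutive* fixations
  covering the three distinct cells of a row/column **in any order**;
  consecutiveness and coverage are required, ordering is not.  An
  order-strict variant (left-to-right / top-to-bottom) is behind
  `order_strict=True`.
* **Off-AOI fixations** break encoding windows (a sweep must be unbroken)
  but are transparent for toggle adjacency (a blink between matrix and
  array is still one consultation).  Both choices are flags
  (`toggles_skip_off_aoi`).
* **Repeated fixations** on the same AOI are collapsed before toggle
  counting only — re-fixating a cell creates no transition — but not
  before encoding windows, where a repeat genuinely breaks a sweep.
* **Response time** is total detected AOI fixation time, not wall-clock;
  the toggle rate uses this denominator, so `toggle_rate × response_time =
  n_toggles` exactly.
* **Censoring.** Trials with no array fixation get `time_to_first_toggle =
  response_time` with a censored flag and are kept (dropping them would
  bias against constructive matchers); a sensitivity flag can drop them.
* Zero-denominator trials (no AOI time; no matrix time) yield NaN and are
  dropped with a warning rather than silently zeroed.

Reliability of each index is raw Cronbach's α over trials in fixed task
order (items = trials, rows = participants, listwise deletion); note raw α
is attenuated when trial variances differ — equal-variance perfectly
correlated trials give exactly 1.

## 3. Scoring and difficulty

Accuracy is percent correct over retained trials; the chance level for
k options is `100/k` (12.5% at the default 8).  The **relational score**
credits the number of matrix relations the chosen option embodies, summed
over trials (`per_relation_credit` rescales it); published rubrics for
this score are only partially printed, so ours is a labelled
reconstruction.  Errors are classified with fixed precedence `duplicate >
novel_feature > partial > other`, giving a single label per response and
category counts that sum to the retained trials.  Item difficulty is
`100 − group mean % correct`, computed per group because the same item can
be trivial for adults and hard for 6-year-olds.

## 4. Statistical pipeline

* Outlier trimming: single pass, `|v − mean| > 2.5 SD` within group, per
  index and per analysis.
* Group comparisons: Welch t by default (pooled-variance behind a flag);
  variance homogeneity by Levene's test with median centering
  (Brown–Forsythe; mean centering available).  A data-quality covariate
  (valid fraction) can be partialled out via OLS.
* Correlations: Pearson r with Fisher-z 95% CI and
  `t = r·sqrt((n−2)/(1−r²))`.
* Trial-level models: logistic `accuracy ~ index + difficulty +
  (1 | participant)`, fit by maximum likelihood with Gauss–Hermite
  quadrature (15 nodes; `matgaze.glmm`).  Wald z comes from the observed
  information (numerical Hessian); non-convergent fits are flagged and not
  reported.  This module exists because no installed Python library offers
  ML GLMMs; it is validated against data simulated from its own model and
  holds the nominal Wald type-I error at α = .05 in the acceptance suite.
* Adaptation slopes: `index ~ difficulty + (difficulty | participant)` —
  linear mixed model (statsmodels `MixedLM`, REML) for continuous indices,
  logistic with correlated-free random intercept + slope for the binary
  encoding/integration flags (link choice for binary indices is not
  settled in the literature; `link="linear"` forces a linear probability
  model).  The difficulty predictor is internally standardized for
  optimizer stability and slopes are rescaled to per-percent units.  The
  extracted per-participant conditional slopes (fixed + posterior-mean
  random effect) are the adaptation indices; on non-convergence the
  routine falls back to flagged per-participant OLS slopes.
* No multiple-comparison correction by default; a Benjamini–Hochberg
  option exists but is off.

## 5. The synthetic cohort generator

The simulator exists so that every stage above can be tested against known
truth.  Per trial it works on the *detected AOI fixation time* clock:

1. total AOI time `S` ~ lognormal around the participant's typical solving
   time, inflated by `exp(0.008·(difficulty − 45))` (harder items take
   longer);
2. the first matrix phase lasts `t1` ~ lognormal around
   `first_toggle_mean`; by construction measured time-to-first-toggle
   equals `t1`;
3. the number of transitions is `1 + Poisson(max(0, λ·S − 1))`, so the
   expected measured toggle rate equals the configured intensity `λ`
   (every simulated trial ends up consulting the answers at least once,
   as a respondent must);
4. remaining time is split into alternating matrix/array phases
   (array dwells shorter by `array_dwell_weight`), each filled with
   lognormal fixation durations floored at 100 ms that sum *exactly* to
   the phase duration;
5. matrix gaze wanders as a sticky Markov chain over the nine cells
   (`stay_prob = 0.55`, jump weights tilted by `early_cell_weight`);
   with probability `p_scan` a row sweep is planted, and independently a
   column sweep.  Wandering also produces occasional accidental sweeps —
   as real scanpaths do — at a rate of roughly 10–15% of trials, recorded
   against the latent truth table;
6. difficulty moves `logit(p_scan)` by `adapt_scan_slope` and `log λ` by
   `adapt_toggle_slope` per percent;
7. off-AOI gaps are inserted so the per-trial valid fraction is exactly
   `1 − missing` (missing ~ Beta around `missing_frac`).

Steps 2, 3 and 7 make the calibration targets exact in expectation:
configured toggle intensity, first-toggle latency and missing fraction are
recovered by the measurement pipeline without construction bias.

**Responses.**  A logistic gate on the *realized* trial indices decides
whether the correct option is found: encoding (+2.2, plus +0.03 per
difficulty percent — scanning pays off most on harder multi-relation
items, while easy items yield to pattern completion), integration (+0.4),
toggle rate (−5.5 /s⁻¹), time to first toggle (+0.5 /s), proportion matrix
time (+1.2), difficulty (−0.10 per percent), all centered at reference
values.  If the gate fails, the error mass is split among duplicate /
novel-feature / partial / other options, with the duplicate weight growing
with toggle rate (heavy answer-consulters drift toward perceptual
matches).  The strong couplings are deliberate: with 24 trials, observed
accuracy SDs of ~16–24 points and index–performance correlations of
.4–.7 — the magnitudes this literature reports — require effects of this
size; weak couplings produce cohorts in which no analysis has power.

**Individual differences.**  Participant parameters are drawn around group
means on transformed scales (logit for `p_scan`, log for rates and times,
with the log-scale mean shifted so arithmetic means match the configured
values).  Two structural correlations define the adaptation ground truth:
a participant's adaptation slope correlates 0.9 with their baseline level
(adaptive scanners scan more overall; adaptive togglers toggle more), and
the standardized slope deviations feed the accuracy intercept directly
(±0.7 / −0.55 logit per SD) — the generator's expression of the claim that
adapting strategy to difficulty marks better reasoners, not just a
statistical artifact of baseline levels.  The direct difficulty penalty is
set strong enough (−0.10) that items remain behaviorally hard despite
adaptive strategy; without it, strategy adaptation cancels the difficulty
gradient and the behavioural difficulty parameter decouples from design
difficulty.

**Item bank.**  24 items in three sets of eight with rising base
difficulty (25/45/65); each set holds three 1-relation, three 2-relation
and two 3-relation items (the final, logical-rule item is treated as a
3-relation stand-in).  Each item offers 8 options: one correct (matching
all relations), one duplicate, one novel-feature, and five with cycling
partial matches.

**Default groups** emulate a developmental study: 6-year-old-like
(`p_scan .10`, `λ .47 s⁻¹`, first toggle 2.2 s, solving 7.6 s, 43%
missing, accuracy ≈ 34%), 9-year-old-like (.32, .38, 3.9 s, 8.9 s, 31%,
≈ 75%) and adult-like (.55, .27, 8.0 s, 21.7 s, 24%, ≈ 51% on a harder
set), n = 40 each.  Accuracy intercepts were solved numerically once to
hit those group means and then frozen.

**What the simulator does *not* emulate:** smooth pursuit and drift,
calibration error that varies over a session, anticipatory or stimulus-
driven saccade dynamics, strategy switching *within* a trial (sweep and
toggle processes are stationary given the item), and item content (options
are feature flags, not rendered matrices).  Tests passing on synthetic
cohorts therefore validate the measurement and inference machinery, not
claims about any particular human population.

## 6. Problem sizes and seeds

The acceptance suite runs Monte-Carlo batches sized to make each property
decisive while keeping the suite desk-scale: 500 cohorts (n = 40) for the
sign-structure checks and 500 null cohorts at the full default cohort size
(n = 120, where the |r| < 0.2 calibration band has ~97% coverage); 200
cohorts for item-level trend signs; 40 for adaptation–performance signs;
6 for slope recovery (mean correlation reported); 5 000 replicates at
20 participants × 12 trials for the Wald and Levene type-I calibrations.
All seeds are fixed constants in the tests; `scripts/acceptance.py` derives
every stream from its `--seed` argument.

## 7. Known limitations

* The Gauss–Hermite GLMM uses non-adaptive quadrature with independent
  random effects; very large random-effect variances (SD ≳ 3 on the logit
  scale) would need more nodes or adaptive centering.
* Binary-index adaptation slopes are weakly identified from 24 Bernoulli
  trials; their extraction correlates ~0.5–0.65 with truth at default
  noise (versus ~0.85 for continuous indices), which is an information
  limit, not an estimator defect.
* Raw-sample rasterisation plus re-detection recovers fixation *time*
  per AOI faithfully but can merge or split individual fixations at
  boundaries; sequence-exact tests therefore run on fixation tables.
* `exclude_trials_participants` implements a single valid-fraction rule;
  studies with manual drift correction or per-trial inspection will need
  their own exclusion columns upstream.
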