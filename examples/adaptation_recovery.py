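"""Recover each simulated participant's difficulty-adaptation slope.

The generator draws a per-participant slope of log toggle intensity on item
difficulty; the analysis refits a linear mixed model with random slopes and
extracts the conditional participant slopes.  Their correlation with the
generating truth is the parameter-recovery check that validates the whole
adaptation analysis.
"""

import dataclasses

import numpy as np

import matgaze as mg
from matgaze.scoring import item_difficulty
from matgaze.stats import adaptation_slopes

cfg = mg.default_config(n_per_group=40, seed=3)
cfg = dataclasses.replace(cfg, groups=(cfg.groups[0],))
cohort = mg.simulate_cohort(cfg, seed=3, light=True)

trials = cohort.trial_indices.merge(
    cohort.responses[["participant", "trial", "correct"]],
    on=["participant", "trial"],
)
diff = item_difficulty(cohort.responses)
trials = trials.merge(
    diff.rename(columns={"item": "trial"})[["trial", "difficulty"]], on="trial"
)

slopes = adaptation_slopes(trials, "toggle_rate")
merged = slopes.merge(cohort.truth_participants, on="participant")
r = np.corrcoef(merged["slope"], merged["adapt_toggle_slope"])[0, 1]

print(f"fitted by: {slopes['method'].iloc[0]} "
      f"(converged: {bool(slopes['converged'].iloc[0])})")
print(f"fixed slope of toggle rate on difficulty: "
      f"{slopes['fixed_slope'].iloc[0]:+.5f} per difficulty percent")
print(f"correlation of extracted vs true participant slopes: r = {r:.2f}")
print()
print("An r well above zero means the random-slope model separates real")
print("between-person differences in difficulty adaptation from trial noise")
print("at 24 items per participant; the shrinkage of the conditional slopes")
print("keeps noisy participants near the fixed effect.")
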