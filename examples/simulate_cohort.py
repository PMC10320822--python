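"""Simulate the default three-group developmental cohort and summarise it.

Generates 6-year-old-like, 9-year-old-like and adult-like groups (40
simulated participants each, 24 matrix items) and prints the group-level
descriptives of strategy and performance -- the shape of a classic
"Table 1" in this literature.
"""

import matgaze as mg

cfg = mg.default_config(n_per_group=40, seed=42)
cohort = mg.simulate_cohort(cfg, seed=42, light=True)

parts = mg.aggregate_participants(cohort.trial_indices, cohort.responses)
parts = parts.merge(
    cohort.responses[["participant", "group"]].drop_duplicates(), on="participant"
)

cols = [
    "percent_correct",
    "pct_encoding",
    "pct_integration",
    "toggle_rate",
    "time_to_first_toggle",
    "prop_matrix_time",
    "valid_fraction",
]
summary = parts.groupby("group")[cols].mean().round(2)
print(summary.T)
print()
print("Scanning (encoding/integration) and the latency to first consult the")
print("answers rise with age while the toggle rate falls: the simulated")
print("cohorts shift from response elimination toward constructive matching,")
print("and accuracy tracks that shift.")
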