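"""Propensity matching, balanced 80:20 split and feature normalisation.

Cases are matched to controls on gestational age, fetal sex and trace
duration; the matched dataset is split stratified on outcome, gestational
week, duration bin and sex; features are normalised with training-fitted
parameters only.
"""

from ctgrisk import (
    SimulationConfig,
    estimate_propensity,
    fit_transforms,
    apply_transforms,
    match_without_replacement,
    simulate_records,
    stratified_split,
)
from ctgrisk.pipeline import features_frame
from ctgrisk.simulate import simulate_cohort
from ctgrisk.features import extract_features

config = SimulationConfig(n_npo=150, n_apo=150, seed=5)
traces, records, _ = simulate_cohort(config)
for trace, rec in zip(traces, records):
    rec.features = extract_features(trace).as_dict()

scores = estimate_propensity(records)
matched = match_without_replacement(scores, records)
print(f"matched pairs: {len(matched.pairs)}, "
      f"unmatched cases: {len(matched.unmatched_cases)}")
for cov, before in matched.smd_before.items():
    print(f"  SMD {cov}: {before:.3f} -> {matched.smd_after[cov]:.3f}")

keep = sorted({i for pair in matched.pairs for i in pair}
              | {i for i, r in enumerate(records) if r.outcome == 1})
dataset = [records[i] for i in keep]
split = stratified_split(dataset, fraction=0.8, seed=0)
print(f"split: {len(split.train)} train / {len(split.validation)} validation")

train_df = features_frame([dataset[i] for i in split.train])
params = fit_transforms(train_df)
transformed = apply_transforms(params, train_df)
print("normalisation rules (z-score for symmetric, min-max for skewed):")
for name, rule in params.rules.items():
    print(f"  {name}: {rule} (skewness {params.skewness[name]:+.2f})")
print("training z-scored columns now have mean 0 / sd 1; min-max in [0, 1].")
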