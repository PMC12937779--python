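"""Apply the plausibility filters and cohort-construction rules.

Builds a small cohort, shows which traces the QC rules exclude and how the
repeat-recording and 7-days-before-delivery rules prune the record list.
"""

import dataclasses

from ctgrisk import (
    SimulationConfig,
    extract_features,
    first_trace_per_week,
    plausibility_filter,
    simulate_cohort,
    temporal_window_filter,
)

config = SimulationConfig(n_npo=20, n_apo=20, seed=3,
                          days_before_delivery_range=(0, 12))
traces, records, _ = simulate_cohort(config)

kept = []
for trace, rec in zip(traces, records):
    fv = extract_features(trace)
    result = plausibility_filter(fv, rec.trace_id)
    if result.passed:
        rec.features = fv.as_dict()
        kept.append(rec)
    else:
        print(f"excluded {rec.trace_id}: {result.failed_rules}")
print(f"QC retained {len(kept)}/{len(records)} traces")

# a duplicate recording in the same gestational week is dropped
dup = dataclasses.replace(kept[0], trace_id="duplicate",
                          gestational_age_days=kept[0].gestational_age_days + 1)
n_before = len(kept) + 1
kept = first_trace_per_week(kept + [dup])
print(f"repeat-recording rule: {n_before} -> {len(kept)}")

# adverse-outcome traces acquired > 7 days before delivery are removed
kept = temporal_window_filter(kept)
print(f"7-day temporal window: kept {len(kept)} records "
      f"(every remaining APO trace is within a week of delivery)")
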