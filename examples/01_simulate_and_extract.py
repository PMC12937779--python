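"""Simulate one antepartum FHR trace and extract its seven features.

The generator plants a known baseline, accelerations/decelerations, and
high/low-variation episodes; extraction should recover them.  The printed
pairs compare the planted value with the extracted one.
"""

from ctgrisk import SimulationConfig, extract_features, simulate_trace

config = SimulationConfig()
trace, truth = simulate_trace(config, cohort="NPO", seed=7)
features = extract_features(trace)

print(f"trace: {trace.duration_min:.0f} min at {trace.sampling_rate:.0f} Hz, "
      f"{trace.missing_mask.mean() * 100:.1f}% signal loss")
print(f"{'feature':>20} {'planted':>9} {'extracted':>10}")
for name in ("basal_fhr", "accelerations", "decelerations", "most_lost_beats",
             "stv", "high_variation_min", "low_variation_min"):
    print(f"{name:>20} {truth.features[name]:>9.2f} "
          f"{getattr(features, name):>10.2f}")
print()
print("basal FHR is in bpm, STV in ms of pulse-interval difference,")
print("episode times in minutes; lost beats = deceleration depth x duration.")
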