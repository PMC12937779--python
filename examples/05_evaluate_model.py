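"""Evaluate a trained risk model: ROC, calibration, operating points,
decision curve and stratified AUCs.

Sensitivity/specificity/F1 are percentages; Cohen's kappa is on the x100
scale.  Net benefit compares acting on the model against treating everyone
(treat-all) or no one (treat-none) at each risk threshold.
"""

import numpy as np

from ctgrisk import (
    ModelSpec,
    bootstrap_ci,
    brier,
    decision_curve,
    fit_final,
    operating_points,
    rank_auc,
    roc_and_auc,
    stratified_auc,
)
from ctgrisk.features import FeatureVector, extract_features
from ctgrisk.simulate import SimulationConfig, simulate_cohort

config = SimulationConfig(n_npo=250, n_apo=250, seed=4)
traces, records, _ = simulate_cohort(config)
X = np.array([[extract_features(t).as_dict()[k]
               for k in FeatureVector.FEATURE_NAMES] for t in traces])
y = np.array([r.outcome for r in records])
weeks = np.array([r.gestational_week for r in records])

train = np.arange(len(y)) % 5 != 0  # simple 80:20 holdout for the example
model = fit_final(ModelSpec("random_forest", seed=0), X[train], y[train],
                  {"n_estimators": 200})
p = model.predict_proba(X[~train])
y_val, weeks_val = y[~train], weeks[~train]

roc = roc_and_auc(p, y_val)
lo, hi = bootstrap_ci(rank_auc, p, y_val, B=500, seed=0)
print(f"validation AUC {roc.auc:.3f} (95% CI {lo:.3f}-{hi:.3f}), "
      f"Brier {brier(p, y_val):.3f}")

for point in operating_points(p, y_val):
    print(f"{point.name:>7}: threshold {point.threshold_pct:5.1f}%  "
          f"sens {point.sensitivity_pct:5.1f}%  spec {point.specificity_pct:5.1f}%  "
          f"F1 {point.f1_pct:5.1f}  kappa {point.kappa:5.1f}")

dc = decision_curve(p, y_val)
print(f"net benefit exceeds treat-all for thresholds in "
      f"{dc.dominates_treat_all}, treat-none in {dc.dominates_treat_none}")

per_week = stratified_auc(p, y_val, weeks_val)
print(f"per-gestational-week AUC: median {per_week['summary']['median_auc']:.3f} "
      f"over {per_week['summary']['n_defined']} weeks")
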