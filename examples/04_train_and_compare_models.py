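"""Tune and cross-validate classifier families, then compare them.

Two families are tuned by sequential model-based (Bayesian) search on
10-fold balanced cross-validation; the fold AUC vectors are compared with
Kruskal-Wallis and pairwise Mann-Whitney tests at alpha = 0.01.
"""

import numpy as np

from ctgrisk import ModelSpec, compare_models, cross_validate, make_folds, tune
from ctgrisk.features import FeatureVector, extract_features
from ctgrisk.simulate import SimulationConfig, simulate_cohort

config = SimulationConfig(n_npo=150, n_apo=150, seed=2)
traces, records, _ = simulate_cohort(config)
X = np.array([[extract_features(t).as_dict()[k]
               for k in FeatureVector.FEATURE_NAMES] for t in traces])
y = np.array([r.outcome for r in records])

folds = make_folds([(int(v),) for v in y], k=10, seed=0)
results = []
for family in ("logistic_regression", "random_forest"):
    spec = ModelSpec(family, seed=0)
    best, log = tune(spec, X, y, folds, budget=6, seed=0)
    cv = cross_validate(spec, X, y, folds, best)
    results.append(cv)
    print(f"{family}: tuned {best}")
    print(f"  mean fold AUC {cv.mean_auc:.3f} (median {cv.median_auc:.3f})")

report = compare_models(results)
print(f"ranking: {report['ranking']}")
print(f"Kruskal-Wallis p = {report['kruskal']['p']:.4f}")
for (a, b), pair in report["pairwise"].items():
    verdict = "differs" if pair["significant"] else "no difference"
    print(f"  {a} vs {b}: U={pair['U']:.0f}, p={pair['p']:.4f} ({verdict} at 0.01)")
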