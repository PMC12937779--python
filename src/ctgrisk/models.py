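"""Classifier families, balanced cross-validation and model comparison.

Six families are supported: decision tree, Gaussian naive Bayes, logistic
regression, random forest, support vector machine and gradient-boosted trees
(XGBoost).  Hyperparameters are found by sequential model-based (Bayesian)
optimisation of the mean fold AUC on 10 folds balanced for outcome,
gestational age, trace duration and fetal sex; models are compared with a
Kruskal-Wallis omnibus test and pairwise two-sided Mann-Whitney U tests at
a significance threshold of 0.01, on identical folds so the comparison is
paired on data.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kruskal, mannwhitneyu
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .errors import ConfigError, ValidationError
from .tuning import Integer, Real, SearchSpace, TrialLog, maximize

logger = logging.getLogger(__name__)

MODEL_FAMILIES = (
    "decision_tree",
    "gaussian_naive_bayes",
    "logistic_regression",
    "random_forest",
    "support_vector_machine",
    "gradient_boosted_trees",
)

ENSEMBLE_FAMILIES = ("random_forest", "gradient_boosted_trees")

COMPARISON_ALPHA = 0.01

# Desk-scale search spaces; every bound finite and overridable per run.
DEFAULT_SPACES: dict[str, SearchSpace] = {
    "decision_tree": {
        "max_depth": Integer(2, 20),
        "min_samples_leaf": Integer(1, 50, log=True),
    },
    "gaussian_naive_bayes": {
        "var_smoothing": Real(1e-12, 1e-3, log=True),
    },
    "logistic_regression": {
        "C": Real(1e-3, 1e3, log=True),
    },
    "random_forest": {
        "n_estimators": Integer(100, 400),
        "max_depth": Integer(3, 20),
        "min_samples_leaf": Integer(1, 20, log=True),
        "max_features": Real(0.2, 1.0),
    },
    "support_vector_machine": {
        "C": Real(1e-2, 1e2, log=True),
        "gamma": Real(1e-3, 1e1, log=True),
    },
    "gradient_boosted_trees": {
        "n_estimators": Integer(50, 400),
        "max_depth": Integer(2, 8),
        "learning_rate": Real(0.01, 0.3, log=True),
        "subsample": Real(0.5, 1.0),
    },
}


@dataclass
class ModelSpec:
    family: str
    space: SearchSpace = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}")
        if not self.space:
            self.space = dict(DEFAULT_SPACES[self.family])


def build_estimator(spec: ModelSpec, params: dict | None = None):
    """Instantiate the scikit-learn / XGBoost estimator for a spec."""
    p = dict(spec.params)
    if params:
        p.update(params)
    seed = spec.seed
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **p)
    if spec.family == "gaussian_naive_bayes":
        return GaussianNB(**p)
    if spec.family == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed, **p)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **p)
    if spec.family == "support_vector_machine":
        return SVC(random_state=seed, **p)
    return XGBClassifier(
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
        verbosity=0,
        **p,
    )


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Ranking scores: probabilities where available, else margins."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


# ---------------------------------------------------------------------------
# folds


def make_folds(
    keys: list[tuple], k: int = 10, seed: int = 0
) -> np.ndarray:
    """Assign records to k folds balanced on the stratification keys.

    Within each stratum, shuffled members are dealt round-robin starting from
    a rotating offset, so per-fold class proportions are within one record of
    the global proportion per stratum.  Deterministic given seed.
    """
    n = len(keys)
    if k < 2 or k > n:
        raise ConfigError(f"cannot make {k} folds from {n} records")
    rng = np.random.default_rng(seed)
    strata: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        strata.setdefault(key, []).append(i)
    folds = np.empty(n, dtype=int)
    offset = 0
    for key in sorted(strata.keys(), key=repr):
        idx = list(strata[key])
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[i] = (offset + j) % k
        offset = (offset + len(idx)) % k
    return folds


def folds_fingerprint(folds: np.ndarray) -> str:
    return hashlib.sha256(np.asarray(folds, dtype=np.int64).tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cross-validation and tuning


@dataclass
class CVResult:
    family: str
    fold_aucs: np.ndarray
    params: dict
    folds_id: str

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def median_auc(self) -> float:
        return float(np.median(self.fold_aucs))


def cross_validate(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, folds: np.ndarray,
    params: dict | None = None,
) -> CVResult:
    """Per-fold validation AUC for one configuration on fixed folds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite features passed to cross_validate")
    aucs = []
    for f in np.unique(folds):
        test = folds == f
        model = build_estimator(spec, params)
        model.fit(X[~test], y[~test])
        if len(np.unique(y[test])) < 2:
            raise ValidationError(f"fold {f} contains a single class")
        aucs.append(roc_auc_score(y[test], _scores(model, X[test])))
    return CVResult(
        family=spec.family,
        fold_aucs=np.array(aucs),
        params=dict(params or {}),
        folds_id=folds_fingerprint(folds),
    )


def tune(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    budget: int = 50,
    seed: int = 0,
) -> tuple[dict, list[TrialLog]]:
    """Bayesian search for the configuration maximising mean fold AUC."""

    def objective(params: dict) -> float:
        return cross_validate(spec, X, y, folds, params).mean_auc

    return maximize(objective, spec.space, budget=budget, seed=seed)


def compare_models(results: list[CVResult]) -> dict:
    """Rank models and test AUC differences across their fold AUCs.

    Omnibus Kruskal-Wallis across all models, then pairwise two-sided
    Mann-Whitney U at alpha = 0.01.  All results must share identical fold
    definitions so the comparison is paired on data.
    """
    if len(results) < 2:
        logger.warning("model comparison skipped: need at least 2 models")
        return {"skipped": True, "ranking": [r.family for r in results]}
    ids = {r.folds_id for r in results}
    if len(ids) > 1:
        raise ValidationError("model comparison requires identical fold definitions")
    ranking = sorted(results, key=lambda r: (-r.mean_auc, r.family))
    groups = [r.fold_aucs for r in results]
    try:
        kw_stat, kw_p = kruskal(*groups)
    except ValueError:  # all values identical
        kw_stat, kw_p = 0.0, 1.0
    pairwise = {}
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            a, b = results[i], results[j]
            if np.array_equal(a.fold_aucs, b.fold_aucs):
                u, p = float(len(a.fold_aucs) ** 2 / 2), 1.0
            else:
                u, p = mannwhitneyu(a.fold_aucs, b.fold_aucs, alternative="two-sided")
            pairwise[(a.family, b.family)] = {
                "U": float(u),
                "p": float(p),
                "significant": bool(p < COMPARISON_ALPHA),
            }
    return {
        "skipped": False,
        "ranking": [r.family for r in ranking],
        "mean_auc": {r.family: r.mean_auc for r in results},
        "median_auc": {r.family: r.median_auc for r in results},
        "kruskal": {"statistic": float(kw_stat), "p": float(kw_p)},
        "pairwise": pairwise,
        "alpha": COMPARISON_ALPHA,
    }


# ---------------------------------------------------------------------------
# final model


@dataclass
class TrainedModel:
    """A fitted classifier emitting probabilities in [0, 1].

    Margin-based families (SVM) get a monotone logistic link fitted on
    out-of-fold decision values, so probability-based evaluation (Brier,
    decision curves) is meaningful for every family.
    """

    spec: ModelSpec
    estimator: object
    calibrator: LogisticRegression | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.calibrator is not None:
            margins = self.estimator.decision_function(X)
            return self.calibrator.predict_proba(margins.reshape(-1, 1))[:, 1]
        return self.estimator.predict_proba(X)[:, 1]


def fit_final(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    params: dict | None = None,
    folds: np.ndarray | None = None,
) -> TrainedModel:
    """Fit the selected configuration on the full training set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite features passed to fit_final")
    model = build_estimator(spec, params)
    model.fit(X, y)
    calibrator = None
    if not hasattr(model, "predict_proba"):
        if folds is None:
            folds = make_folds([(int(v),) for v in y], k=min(5, max(2, len(y) // 2)),
                               seed=spec.seed)
        oof = np.empty(len(y))
        for f in np.unique(folds):
            test = folds == f
            m = build_estimator(spec, params)
            m.fit(X[~test], y[~test])
            oof[test] = m.decision_function(X[test])
        calibrator = LogisticRegression(max_iter=1000)
        calibrator.fit(oof.reshape(-1, 1), y)
    return TrainedModel(spec=spec, estimator=model, calibrator=calibrator)


def feature_importances(model: TrainedModel, feature_names: list[str]) -> dict[str, float]:
    """Impurity-based importances of a tree-ensemble model, normalised to 1."""
    if model.spec.family not in ENSEMBLE_FAMILIES:
        raise ValidationError(
            f"feature importances require a tree-ensemble model, got {model.spec.family}"
        )
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    if imp.sum() <= 0:
        imp = np.full(len(feature_names), 1.0)
    imp = imp / imp.sum()
    return {name: float(v) for name, v in zip(feature_names, imp)}
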