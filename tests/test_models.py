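"""Folds, tuning, model comparison, final fits and importances."""

import numpy as np
import pytest

from ctgrisk.errors import ConfigError, ValidationError
from ctgrisk.models import (
    CVResult,
    ModelSpec,
    compare_models,
    cross_validate,
    feature_importances,
    fit_final,
    folds_fingerprint,
    make_folds,
    tune,
)
from ctgrisk.tuning import Categorical, Integer, Real, maximize


def toy_data(n=200, d=4, informative=2, seed=0, separation=2.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, d))
    X[:, :informative] += separation * y[:, None]
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestFolds:
    def test_balanced_partition(self):
        keys = [(i % 2,) for i in range(100)]
        folds = make_folds(keys, k=10, seed=0)
        assert sorted(np.unique(folds)) == list(range(10))
        for f in range(10):
            sel = folds == f
            assert sel.sum() == 10
            assert sum(keys[i][0] for i in np.flatnonzero(sel)) == 5

    def test_deterministic(self):
        keys = [(i % 3, i % 2) for i in range(57)]
        assert np.array_equal(make_folds(keys, 10, seed=4), make_folds(keys, 10, seed=4))

    def test_union_is_everything(self):
        keys = [(i % 5,) for i in range(83)]
        folds = make_folds(keys, k=10, seed=1)
        assert len(folds) == 83 and folds.min() >= 0 and folds.max() <= 9

    def test_too_many_folds_rejected(self):
        with pytest.raises(ConfigError):
            make_folds([(0,)] * 5, k=10)


class TestTuning:
    def test_budget_one_returns_single_point(self):
        calls = []

        def obj(params):
            calls.append(params)
            return 1.0

        best, log = maximize(obj, {"x": Real(0.0, 1.0)}, budget=1, seed=0)
        assert len(calls) == 1 and len(log) == 1
        assert best == calls[0]

    def test_single_point_space(self):
        space = {"x": Integer(3, 3), "kind": Categorical(("a",))}
        best, _ = maximize(lambda p: 0.5, space, budget=3, seed=0)
        assert best == {"x": 3, "kind": "a"}

    def test_deterministic_given_seed(self):
        space = {"x": Real(-2, 2), "y": Real(-2, 2)}

        def obj(p):
            return -(p["x"] - 0.3) ** 2 - (p["y"] + 0.5) ** 2

        a, _ = maximize(obj, space, budget=12, seed=7)
        b, _ = maximize(obj, space, budget=12, seed=7)
        assert a == b

    def test_finds_good_region(self):
        space = {"x": Real(0, 1)}
        best, _ = maximize(lambda p: -(p["x"] - 0.62) ** 2, space, budget=20, seed=1)
        assert abs(best["x"] - 0.62) < 0.15

    def test_all_failures_raise(self):
        def obj(p):
            raise RuntimeError("boom")

        with pytest.raises(ConfigError):
            maximize(obj, {"x": Real(0, 1)}, budget=3, seed=0)

    def test_tuned_not_worse_than_default(self):
        X, y = toy_data(n=200, separation=1.0, seed=3)
        folds = make_folds([(int(v),) for v in y], k=5, seed=0)
        spec = ModelSpec("decision_tree", seed=0)
        best, _ = tune(spec, X, y, folds, budget=10, seed=0)
        tuned_auc = cross_validate(spec, X, y, folds, best).mean_auc
        default_auc = cross_validate(spec, X, y, folds, {}).mean_auc
        assert tuned_auc >= default_auc - 0.01


class TestCrossValidation:
    def test_fold_aucs_shape_and_range(self):
        X, y = toy_data()
        folds = make_folds([(int(v),) for v in y], k=10, seed=0)
        res = cross_validate(ModelSpec("logistic_regression"), X, y, folds)
        assert len(res.fold_aucs) == 10
        assert np.all((res.fold_aucs >= 0) & (res.fold_aucs <= 1))

    def test_every_family_runs(self):
        X, y = toy_data(n=120)
        folds = make_folds([(int(v),) for v in y], k=4, seed=0)
        for family in ("decision_tree", "gaussian_naive_bayes",
                       "logistic_regression", "random_forest",
                       "support_vector_machine", "gradient_boosted_trees"):
            params = {"n_estimators": 20} if family in (
                "random_forest", "gradient_boosted_trees") else {}
            res = cross_validate(ModelSpec(family), X, y, folds, params)
            assert res.mean_auc > 0.8  # well-separated toy problem


class TestComparison:
    def _cv(self, family, aucs, folds_id="f"):
        return CVResult(family, np.array(aucs), {}, folds_id)

    def test_identical_folds_required(self):
        with pytest.raises(ValidationError):
            compare_models([self._cv("a", [0.8] * 10, "f1"),
                            self._cv("b", [0.8] * 10, "f2")])

    def test_identical_aucs_p_one(self):
        rep = compare_models([self._cv("logistic_regression", [0.8] * 10),
                              self._cv("decision_tree", [0.8] * 10)])
        pair = rep["pairwise"][("logistic_regression", "decision_tree")]
        assert pair["p"] == 1.0 and not pair["significant"]

    def test_fully_separated_ranks(self):
        # {0.9 x10} vs {0.6 x10}: U = 100 by exhaustive rank-sum
        rep = compare_models([self._cv("random_forest", [0.9] * 10),
                              self._cv("decision_tree", [0.6] * 10)])
        pair = rep["pairwise"][("random_forest", "decision_tree")]
        assert pair["U"] == 100.0
        assert pair["significant"]
        assert rep["ranking"][0] == "random_forest"

    def test_single_model_skipped(self):
        rep = compare_models([self._cv("random_forest", [0.9] * 10)])
        assert rep["skipped"]


class TestFinalFit:
    def test_separable_training_auc_one(self):
        X, y = toy_data(n=100, separation=8.0)
        model = fit_final(ModelSpec("logistic_regression"), X, y)
        from ctgrisk.metrics import rank_auc

        assert rank_auc(model.predict_proba(X), y) == 1.0

    def test_probabilities_in_unit_interval_all_families(self):
        X, y = toy_data(n=80)
        for family in ("support_vector_machine", "random_forest",
                       "gaussian_naive_bayes"):
            params = {"n_estimators": 20} if family == "random_forest" else {}
            model = fit_final(ModelSpec(family), X, y, params)
            p = model.predict_proba(X)
            assert np.all((p >= 0) & (p <= 1))

    def test_deterministic_predictions(self):
        X, y = toy_data(n=100)
        a = fit_final(ModelSpec("random_forest", seed=3), X, y, {"n_estimators": 30})
        b = fit_final(ModelSpec("random_forest", seed=3), X, y, {"n_estimators": 30})
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_nonfinite_features_rejected(self):
        X, y = toy_data(n=40)
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            fit_final(ModelSpec("logistic_regression"), X, y)

    def test_label_permutation_chance_auc(self):
        # anti-leakage: permuted labels drive CV AUC to 0.5 +/- 0.05
        X, y = toy_data(n=1000, separation=2.0, seed=1)
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        folds = make_folds([(int(v),) for v in y_perm], k=10, seed=0)
        res = cross_validate(ModelSpec("random_forest", seed=0), X, y_perm,
                             folds, {"n_estimators": 50})
        assert abs(res.mean_auc - 0.5) < 0.05


class TestImportances:
    def test_normalised_and_keyed(self):
        X, y = toy_data(n=150, d=5, informative=2)
        model = fit_final(ModelSpec("random_forest"), X, y, {"n_estimators": 50})
        imp = feature_importances(model, [f"f{i}" for i in range(5)])
        assert sum(imp.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in imp.values())

    def test_noise_feature_ranks_last(self):
        X, y = toy_data(n=500, d=3, informative=2, seed=2)
        model = fit_final(ModelSpec("random_forest", seed=0), X, y,
                          {"n_estimators": 100})
        imp = feature_importances(model, ["a", "b", "noise"])
        assert imp["noise"] < imp["a"] and imp["noise"] < imp["b"]

    def test_non_ensemble_rejected(self):
        X, y = toy_data(n=60)
        model = fit_final(ModelSpec("logistic_regression"), X, y)
        with pytest.raises(ValidationError):
            feature_importances(model, ["x"] * X.shape[1])
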