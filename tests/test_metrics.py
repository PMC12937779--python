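"""Evaluation metrics: closed forms, identities and simulation checks."""

import numpy as np
import pandas as pd
import pytest

from ctgrisk.errors import ValidationError
from ctgrisk.metrics import (
    bootstrap_ci,
    brier,
    cohens_d,
    confusion_metrics,
    decision_curve,
    feature_association_tests,
    operating_points,
    rank_auc,
    rank_biserial,
    roc_and_auc,
    stratified_auc,
    subtype_auc,
    trapezoid_auc,
)


class TestAUC:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert rank_auc(scores, labels) == 1.0

    def test_brute_force_pair_count(self):
        scores = np.array([0.9, 0.8, 0.7, 0.1])
        labels = np.array([1, 1, 0, 0])
        pairs = [(c, k) for c in (0.9, 0.8) for k in (0.7, 0.1)]
        oracle = np.mean([1.0 if c > k else 0.5 if c == k else 0.0 for c, k in pairs])
        assert rank_auc(scores, labels) == pytest.approx(oracle, abs=1e-15)

    def test_ties_count_half(self):
        scores = np.array([0.5, 0.5])
        labels = np.array([1, 0])
        assert rank_auc(scores, labels) == 0.5

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10000)
        labels = rng.integers(0, 2, 10000)
        assert rank_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_rank_equals_trapezoid(self):
        rng = np.random.default_rng(1)
        for trial in range(20):
            n = int(rng.integers(10, 300))
            scores = np.round(rng.random(n), 2)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            roc = roc_and_auc(scores, labels)
            assert abs(roc.auc - trapezoid_auc(roc)) < 1e-12

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(2)
        roc = roc_and_auc(rng.random(50), rng.integers(0, 2, 50))
        assert roc.sensitivity[0] == 0.0 and roc.specificity[0] == 1.0
        assert roc.sensitivity[-1] == 1.0 and roc.specificity[-1] == 0.0
        assert np.all(np.diff(roc.sensitivity) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            rank_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1] * 10)
        labels = np.array([1, 1, 0, 0] * 10)
        lo, hi = bootstrap_ci(rank_auc, scores, labels, B=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        scores = np.r_[rng.normal(1, 1, 150), rng.normal(0, 1, 150)]
        labels = np.r_[np.ones(150, int), np.zeros(150, int)]
        auc = rank_auc(scores, labels)
        lo, hi = bootstrap_ci(rank_auc, scores, labels, B=300, seed=0)
        assert lo <= auc <= hi

    def test_more_resamples_stable(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(1, 1, 100), rng.normal(0, 1, 100)]
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        a = bootstrap_ci(rank_auc, scores, labels, B=500, seed=1)
        b = bootstrap_ci(rank_auc, scores, labels, B=1000, seed=1)
        assert abs((b[1] - b[0]) - (a[1] - a[0])) < 0.02

    def test_small_b_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_ci(rank_auc, np.array([1.0, 0.0]), np.array([1, 0]), B=10)


class TestOperatingPoints:
    def test_confusion_closed_form(self):
        m = confusion_metrics(tp=40, fn=10, tn=40, fp=10)
        assert m["sensitivity"] == pytest.approx(80.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["kappa"] == pytest.approx(60.0)
        assert m["f1"] == pytest.approx(80.0)

    def test_perfect_classifier(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1] * 25)
        labels = np.array([1, 1, 0, 0] * 25)
        pts = {p.name: p for p in operating_points(scores, labels)}
        y = pts["youden"]
        assert y.sensitivity_pct == 100.0 and y.specificity_pct == 100.0
        assert y.kappa == pytest.approx(100.0)
        assert pts["sens95"].attainable and pts["spec95"].attainable

    def test_random_scores_kappa_near_zero(self):
        rng = np.random.default_rng(5)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        pts = {p.name: p for p in operating_points(scores, labels)}
        assert abs(pts["youden"].kappa) < 10.0  # x100 scale

    def test_unattainable_specificity_flagged(self):
        # 95% sensitivity is always reachable at the lowest threshold, but
        # with a control holding the top score no observed threshold reaches
        # 95% specificity: reported as unattainable, not clamped
        scores = np.array([0.4, 0.4, 0.6, 0.6])
        labels = np.array([0, 0, 1, 1])
        pts = {p.name: p for p in operating_points(scores, labels)}
        assert pts["sens95"].attainable and pts["spec95"].attainable
        scores2 = np.array([0.9, 0.8, 0.7, 0.1])
        labels2 = np.array([0, 1, 1, 0])
        pts2 = {p.name: p for p in operating_points(scores2, labels2)}
        assert pts2["sens95"].attainable
        assert not pts2["spec95"].attainable

    def test_youden_tie_breaks_low_threshold(self):
        # two thresholds with equal Youden index: keep the more sensitive one
        scores = np.array([0.9, 0.7, 0.5, 0.3])
        labels = np.array([1, 1, 0, 0])
        pts = {p.name: p for p in operating_points(scores, labels)}
        assert pts["youden"].threshold_pct == pytest.approx(70.0)


class TestBrierAndDecision:
    def test_brier_closed_forms(self):
        labels = np.array([1, 0, 1, 0])
        assert brier(labels.astype(float), labels) == 0.0
        assert brier(np.full(4, 0.5), labels) == 0.25
        # constant p on prevalence pi: pi (1-p)^2 + (1-pi) p^2
        # at p=0.3, pi=0.5: 0.5 * 0.49 + 0.5 * 0.09 = 0.29
        labels2 = np.array([1, 0] * 50)
        assert brier(np.full(100, 0.3), labels2) == pytest.approx(0.29)

    def test_brier_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            brier(np.array([1.2]), np.array([1]))

    def test_treat_none_zero_and_hand_case(self):
        # N=100, TP=30, FP=10 at pt=0.2 -> NB = 0.3 - 0.1 * 0.25 = 0.275
        p = np.r_[np.full(30, 0.9), np.full(20, 0.05), np.full(10, 0.9),
                  np.full(40, 0.05)]
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        dc = decision_curve(p, y, grid=np.array([0.2]))
        assert dc.treat_none[0] == 0.0
        assert dc.net_benefit[0] == pytest.approx(0.275)

    def test_treat_all_crosses_zero_at_prevalence(self):
        y = np.r_[np.ones(30, int), np.zeros(70, int)]
        dc = decision_curve(np.full(100, 0.5), y, grid=np.array([0.3]))
        assert dc.treat_all[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_classifier_nb_equals_prevalence(self):
        y = np.r_[np.ones(40, int), np.zeros(60, int)]
        p = y.astype(float) * 0.8 + 0.1  # cases 0.9, controls 0.1
        dc = decision_curve(p, y)
        low = dc.thresholds < 0.9
        assert np.allclose(dc.net_benefit[low & (dc.thresholds > 0.1)], 0.4)
        assert np.all(dc.net_benefit <= y.mean() + 1e-12)

    def test_threshold_one_rejected(self):
        with pytest.raises(ValidationError):
            decision_curve(np.array([0.5]), np.array([1]), grid=np.array([1.0]))


class TestStratifiedAUC:
    def test_single_stratum_equals_global(self):
        rng = np.random.default_rng(6)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        out = stratified_auc(scores, labels, np.zeros(200, int))
        assert out["strata"]["0"]["auc"] == pytest.approx(rank_auc(scores, labels))
        assert out["summary"]["median_auc"] == out["strata"]["0"]["auc"]

    def test_one_class_stratum_flagged_undefined(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        strata = np.array(["a", "a", "b", "b"])
        out = stratified_auc(scores, labels, strata)
        assert out["strata"]["a"]["defined"] is False
        assert out["strata"]["a"]["auc"] is None

    def test_gestation_dependent_separation_ordering(self):
        # plant monotone separation across three strata; AUC order follows
        rng = np.random.default_rng(7)
        rows, labels, strata = [], [], []
        for s, sep in enumerate((0.3, 1.0, 2.5)):
            rows += list(rng.normal(0, 1, 200)) + list(rng.normal(sep, 1, 200))
            labels += [0] * 200 + [1] * 200
            strata += [s] * 400
        out = stratified_auc(np.array(rows), np.array(labels), np.array(strata))
        aucs = [out["strata"][str(s)]["auc"] for s in range(3)]
        assert aucs == sorted(aucs)

    def test_subtype_one_vs_all_controls(self):
        rng = np.random.default_rng(8)
        scores = np.r_[rng.normal(2, 1, 50), rng.normal(0, 1, 100)]
        labels = np.r_[np.ones(50, int), np.zeros(100, int)]
        flags = pd.DataFrame({
            "a": np.r_[np.ones(25), np.zeros(25), np.zeros(100)].astype(bool),
            "b": np.zeros(150, dtype=bool),
        })
        out = subtype_auc(scores, labels, flags)
        sel = flags["a"].to_numpy() | (labels == 0)
        assert out["strata"]["a"]["auc"] == pytest.approx(
            rank_auc(scores[sel], labels[sel])
        )
        assert out["strata"]["b"]["defined"] is False


class TestAssociations:
    def test_rank_biserial_closed_form(self):
        # feature with AUC 0.75 -> rank-biserial 0.5
        scores = np.array([3.0, 2.0, 2.5, 1.0])
        labels = np.array([1, 1, 0, 0])
        assert rank_auc(scores, labels) == 0.75
        assert rank_biserial(scores, labels) == pytest.approx(0.5)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "shifted": np.r_[rng.normal(1, 1, 500), rng.normal(0, 1, 500)],
            "null": rng.normal(0, 1, 1000),
        })
        labels = np.r_[np.ones(500, int), np.zeros(500, int)]
        out = feature_association_tests(df, labels)
        assert out.loc["shifted", "p"] < 0.001
        assert out.loc["shifted", "significant"]
        assert out.loc["null", "p"] > 0.001
        assert out.loc["shifted", "effect_kind"] == "cohens_d"
        assert out.loc["shifted", "effect"] == pytest.approx(
            cohens_d(df["shifted"][:500].to_numpy(), df["shifted"][500:].to_numpy())
        )

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(10)
        ps = []
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        for _ in range(100):
            df = pd.DataFrame({"x": rng.normal(size=200)})
            ps.append(feature_association_tests(df, labels).loc["x", "p"])
        assert 0.2 < np.mean(ps) < 0.8
        assert (np.array(ps) < 0.05).mean() < 0.15

    def test_skewed_feature_uses_rank_biserial(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"x": rng.exponential(1, 400) ** 2})
        labels = rng.integers(0, 2, 400)
        out = feature_association_tests(df, labels)
        assert out.loc["x", "effect_kind"] == "rank_biserial"
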