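"""Discrimination, calibration, operating-point and decision-analytic
evaluation of a binary risk model.

AUC is computed with the rank (Mann-Whitney) formulation,
P(score_case > score_control) + 0.5 P(tie), which agrees with trapezoidal
integration of the ROC curve to numerical precision.  Confidence intervals
are percentile bootstrap, stratified by class so resamples preserve
prevalence.  Operating points follow the clinical conventions: the Youden
index (sensitivity + specificity - 1 maximised, ties broken toward the lower
threshold, i.e. higher sensitivity), the highest threshold retaining 95%
sensitivity, and the lowest threshold achieving 95% specificity; sensitivity,
specificity, F1 and Cohen's kappa are reported on a x100 scale.  Decision
curves report net benefit NB(pt) = TP/N - (FP/N) * pt/(1-pt) against
treat-all and treat-none strategies over thresholds 0.01-0.99.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, skew

from .errors import ValidationError

logger = logging.getLogger(__name__)

DECISION_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)
MIN_STRATUM_CASES = 5


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    return labels


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via mean rank of the cases (handles ties exactly)."""
    labels = _check_binary(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def trapezoid_auc(roc: ROCCurve) -> float:
    """Trapezoidal integral of the ROC curve (for cross-checks)."""
    fpr = 1.0 - roc.specificity
    return float(np.trapezoid(roc.sensitivity, fpr))


def roc_and_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC curve over all observed score thresholds, endpoints included."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    auc = rank_auc(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[distinct].astype(float)
    fp = (distinct + 1) - tp
    n1, n0 = float(labels.sum()), float(len(labels) - labels.sum())
    sens = np.r_[0.0, tp / n1]
    spec = np.r_[1.0, 1.0 - fp / n0]
    thresholds = np.r_[np.inf, s[distinct]]
    return ROCCurve(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_ci(
    metric,
    scores: np.ndarray,
    labels: np.ndarray,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI over class-stratified resamples.

    Resamples that collapse to one class (possible for metrics evaluated on
    sub-strata) are redrawn and counted in the log.
    """
    if B < 100:
        raise ValidationError("bootstrap requires B >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(labels == 1)
    idx0 = np.flatnonzero(labels == 0)
    values = []
    redraws = 0
    for _ in range(B):
        for _attempt in range(100):
            take = np.r_[
                rng.choice(idx1, size=len(idx1), replace=True),
                rng.choice(idx0, size=len(idx0), replace=True),
            ]
            try:
                values.append(float(metric(scores[take], labels[take])))
                break
            except ValidationError:
                redraws += 1
        else:
            raise ValidationError("bootstrap resampling failed repeatedly")
    if redraws:
        logger.info("bootstrap: %d degenerate resamples redrawn", redraws)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(values, lo)),
        float(np.quantile(values, 1.0 - lo)),
    )


# ---------------------------------------------------------------------------
# operating points


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Sensitivity, specificity, F1 and Cohen's kappa from a confusion
    matrix, on the x100 reporting scale."""
    n = tp + fn + tn + fp
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    kappa = (po - pe) / (1 - pe) if pe < 1 else 1.0
    return {
        "sensitivity": 100.0 * sens,
        "specificity": 100.0 * spec,
        "f1": 100.0 * f1,
        "kappa": 100.0 * kappa,
    }


@dataclass
class OperatingPoint:
    name: str  # youden | sens95 | spec95
    threshold_pct: float
    sensitivity_pct: float
    specificity_pct: float
    f1_pct: float
    kappa: float
    attainable: bool = True
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def _point_at(scores, labels, threshold) -> dict[str, float]:
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    return confusion_metrics(tp, fn, tn, fp)


def operating_points(
    scores: np.ndarray,
    labels: np.ndarray,
    bootstrap_B: int = 0,
    seed: int = 0,
) -> list[OperatingPoint]:
    """Youden, 95%-sensitivity and 95%-specificity operating points.

    Thresholds are taken from the observed ROC; an unattainable constraint
    (e.g. no threshold reaches 95% sensitivity short of classifying everyone
    positive) is reported with ``attainable=False`` rather than clamped.
    With ``bootstrap_B`` > 0, percentile CIs are attached to each metric
    (the threshold is re-derived within each resample).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    roc = roc_and_auc(scores, labels)
    finite = np.isfinite(roc.thresholds)
    thr = roc.thresholds[finite]
    sens = roc.sensitivity[finite]
    spec = roc.specificity[finite]

    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())
    youden_thr = float(thr[best[-1]])  # lowest threshold on ties

    s95 = np.flatnonzero(sens >= 0.95)
    sens95_thr, sens95_ok = (float(thr[s95[0]]), True) if len(s95) else (float(thr[-1]), False)
    p95 = np.flatnonzero(spec >= 0.95)
    spec95_thr, spec95_ok = (float(thr[p95[-1]]), True) if len(p95) else (float(thr[0]), False)

    defs = [
        ("youden", youden_thr, True),
        ("sens95", sens95_thr, sens95_ok),
        ("spec95", spec95_thr, spec95_ok),
    ]
    points = []
    for name, threshold, ok in defs:
        m = _point_at(scores, labels, threshold)
        point = OperatingPoint(
            name=name,
            threshold_pct=100.0 * threshold,
            sensitivity_pct=m["sensitivity"],
            specificity_pct=m["specificity"],
            f1_pct=m["f1"],
            kappa=m["kappa"],
            attainable=ok,
        )
        if bootstrap_B:
            for key in ("threshold_pct", "sensitivity_pct", "specificity_pct",
                        "f1_pct", "kappa"):
                point.ci[key] = bootstrap_ci(
                    _operating_metric(name, key),
                    scores, labels, B=bootstrap_B, seed=seed,
                )
        points.append(point)
    return points


def _operating_metric(point_name: str, key: str):
    def metric(scores, labels):
        pts = {p.name: p for p in operating_points(scores, labels)}
        return getattr(pts[point_name], key)

    return metric


# ---------------------------------------------------------------------------
# calibration and decision analysis


def brier(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean squared difference between probability and outcome."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("probabilities must lie in [0, 1]")
    labels = _check_binary(labels)
    return float(np.mean((p - labels) ** 2))


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    dominates_treat_all: tuple[float, float] | None
    dominates_treat_none: tuple[float, float] | None


def decision_curve(
    probabilities: np.ndarray,
    labels: np.ndarray,
    grid: np.ndarray = DECISION_GRID,
) -> DecisionCurve:
    """Net benefit of acting on the model versus treat-all / treat-none."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    labels = _check_binary(labels)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid >= 1.0) or np.any(grid <= 0.0):
        raise ValidationError("thresholds must lie strictly inside (0, 1)")
    n = len(labels)
    prevalence = labels.mean()
    nb = np.empty(len(grid))
    for i, pt in enumerate(grid):
        pred = p >= pt
        tp = np.sum(pred & (labels == 1)) / n
        fp = np.sum(pred & (labels == 0)) / n
        nb[i] = tp - fp * pt / (1.0 - pt)
    treat_all = prevalence - (1.0 - prevalence) * grid / (1.0 - grid)
    treat_none = np.zeros_like(grid)

    def dominate_range(other: np.ndarray) -> tuple[float, float] | None:
        above = nb > other + 1e-12
        if not above.any():
            return None
        idx = np.flatnonzero(above)
        return (float(grid[idx[0]]), float(grid[idx[-1]]))

    return DecisionCurve(
        thresholds=grid,
        net_benefit=nb,
        treat_all=treat_all,
        treat_none=treat_none,
        dominates_treat_all=dominate_range(treat_all),
        dominates_treat_none=dominate_range(treat_none),
    )


# ---------------------------------------------------------------------------
# stratified evaluation and feature screening


def stratified_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    strata: np.ndarray,
    min_cases: int = MIN_STRATUM_CASES,
    bootstrap_B: int = 0,
    seed: int = 0,
) -> dict:
    """Per-stratum AUC with optional bootstrap CIs.

    A stratum with one class yields an undefined AUC, reported as such;
    strata with fewer than ``min_cases`` cases are flagged, never silently
    dropped.  The summary reports the median and IQR across defined strata.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    strata = np.asarray(strata)
    out: dict = {"strata": {}, "summary": {}}
    defined = []
    for value in sorted(map(str, np.unique(strata))):
        sel = strata.astype(str) == value
        n_cases = int(labels[sel].sum())
        n_controls = int((~labels[sel].astype(bool)).sum())
        entry: dict = {"n_cases": n_cases, "n_controls": n_controls,
                       "small": n_cases < min_cases}
        if n_cases == 0 or n_controls == 0:
            entry["auc"] = None
            entry["defined"] = False
        else:
            auc = rank_auc(scores[sel], labels[sel])
            entry["auc"] = auc
            entry["defined"] = True
            defined.append(auc)
            if bootstrap_B:
                entry["ci"] = bootstrap_ci(rank_auc, scores[sel], labels[sel],
                                           B=bootstrap_B, seed=seed)
        out["strata"][value] = entry
    if defined:
        out["summary"] = {
            "median_auc": float(np.median(defined)),
            "iqr": (float(np.quantile(defined, 0.25)), float(np.quantile(defined, 0.75))),
            "n_defined": len(defined),
        }
    return out


def subtype_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    subtype_flags: pd.DataFrame,
    bootstrap_B: int = 0,
    seed: int = 0,
) -> dict:
    """Per-subtype AUC: each subtype's cases versus all controls.

    Subtypes co-occur, so a one-vs-all-controls framing is used rather than
    a partition of the cases.
    """
    labels = _check_binary(labels)
    controls = labels == 0
    out: dict = {"strata": {}, "summary": {}}
    defined = []
    for name in subtype_flags.columns:
        is_case = subtype_flags[name].to_numpy(dtype=bool) & (labels == 1)
        sel = is_case | controls
        n_cases = int(is_case.sum())
        entry: dict = {"n_cases": n_cases, "small": n_cases < MIN_STRATUM_CASES}
        if n_cases == 0:
            entry["auc"], entry["defined"] = None, False
        else:
            auc = rank_auc(scores[sel], labels[sel])
            entry["auc"], entry["defined"] = auc, True
            defined.append(auc)
            if bootstrap_B:
                entry["ci"] = bootstrap_ci(rank_auc, scores[sel], labels[sel],
                                           B=bootstrap_B, seed=seed)
        out["strata"][name] = entry
    if defined:
        out["summary"] = {
            "median_auc": float(np.median(defined)),
            "iqr": (float(np.quantile(defined, 0.25)), float(np.quantile(defined, 0.75))),
            "n_defined": len(defined),
        }
    return out


def rank_biserial(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-biserial correlation, equal to 2 AUC - 1."""
    return 2.0 * rank_auc(scores, labels) - 1.0


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    return float((x.mean() - y.mean()) / pooled) if pooled > 0 else 0.0


def feature_association_tests(
    features: pd.DataFrame,
    labels: np.ndarray,
    skew_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Mann-Whitney tests with effect sizes.

    Approximately symmetric features (|skewness| <= threshold, the same rule
    used for normalisation) report Cohen's D; skewed features report the
    rank-biserial correlation (2 AUC - 1).
    """
    labels = _check_binary(labels)
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        cases, controls = x[labels == 1], x[labels == 0]
        if len(cases) < 2 or len(controls) < 2:
            raise ValidationError(f"feature {name}: need >= 2 observations per group")
        if np.ptp(x) == 0:
            logger.warning("feature %s is constant; association undefined", name)
            rows.append({"feature": name, "p": 1.0, "effect": 0.0,
                         "effect_kind": "rank_biserial", "significant": False})
            continue
        _, p = mannwhitneyu(cases, controls, alternative="two-sided")
        if abs(float(skew(x))) > skew_threshold:
            effect = rank_biserial(x, labels)
            kind = "rank_biserial"
        else:
            effect = cohens_d(cases, controls)
            kind = "cohens_d"
        rows.append({"feature": name, "p": float(p), "effect": float(effect),
                     "effect_kind": kind, "significant": bool(p < alpha)})
    return pd.DataFrame(rows).set_index("feature")
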