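"""Propensity-score matching, balanced splitting and feature transformation.

Cases (APO) are matched to controls (NPO) on gestational age at trace
acquisition, fetal sex and trace duration via a logistic propensity model
and greedy nearest-neighbour sampling without replacement, with a caliper of
0.2 standard deviations of the logit score.  The matched dataset is then
split 80:20 stratified on outcome, gestational week, 10-minute duration bin
and fetal sex, and the seven features are normalised with parameters fitted
on the training part only (z-score for approximately symmetric features,
min-max for skewed ones, |skewness| > 1 as the rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import skew
from sklearn.linear_model import LogisticRegression

from .errors import ConfigError, ValidationError
from .features import FeatureVector
from .trace_io import CohortRecord

logger = logging.getLogger(__name__)

MATCH_COVARIATES = ("gestational_age_days", "fetal_sex", "duration_min")
DURATION_BIN_MIN = 10.0
SKEW_THRESHOLD = 1.0
DEFAULT_CALIPER_SD = 0.2


def _covariate_matrix(records: list[CohortRecord]) -> np.ndarray:
    return np.array(
        [
            [r.gestational_age_days, 1.0 if r.fetal_sex == "male" else 0.0, r.duration_min]
            for r in records
        ],
        dtype=float,
    )


def estimate_propensity(records: list[CohortRecord]) -> np.ndarray:
    """Propensity scores in (0, 1) from an additive logistic model.

    Deterministic given the data; zero-variance covariates are dropped with
    a warning rather than failing the fit.
    """
    if not records:
        raise ValidationError("no records to score")
    X = _covariate_matrix(records)
    y = np.array([r.outcome for r in records])
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [MATCH_COVARIATES[i] for i in np.flatnonzero(~keep)]
        logger.warning("propensity model: dropping zero-variance covariates %s", dropped)
    if keep.any() and 0 < y.sum() < len(y):
        Xk = (X[:, keep] - X[:, keep].mean(axis=0)) / X[:, keep].std(axis=0)
        model = LogisticRegression(max_iter=1000)
        model.fit(Xk, y)
        scores = model.predict_proba(Xk)[:, 1]
    else:
        scores = np.full(len(records), float(y.mean()) if len(y) else 0.5)
    return np.clip(scores, 1e-9, 1 - 1e-9)


def standardized_mean_differences(
    records: list[CohortRecord], indices: np.ndarray | None = None
) -> dict[str, float]:
    """Absolute standardized mean difference per matching covariate."""
    if indices is not None:
        records = [records[i] for i in indices]
    X = _covariate_matrix(records)
    y = np.array([r.outcome for r in records], dtype=bool)
    out = {}
    for j, name in enumerate(MATCH_COVARIATES):
        a, b = X[y, j], X[~y, j]
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0) if len(a) > 1 and len(b) > 1 else 0.0
        out[name] = abs(a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
    return out


@dataclass
class MatchedDataset:
    pairs: list[tuple[int, int]]  # (APO index, NPO index) into the input records
    unmatched_cases: list[int]
    smd_before: dict[str, float]
    smd_after: dict[str, float]
    caliper: float

    @property
    def matched_indices(self) -> np.ndarray:
        idx = [i for pair in self.pairs for i in pair]
        return np.array(sorted(idx), dtype=int)


def match_without_replacement(
    scores: np.ndarray,
    records: list[CohortRecord],
    caliper_sd: float = DEFAULT_CALIPER_SD,
) -> MatchedDataset:
    """Greedy nearest-neighbour matching on the logit propensity score.

    Each control is used at most once; cases are processed in descending
    propensity (hardest to match first).  Cases with no control within the
    caliper remain unmatched and are reported, not silently dropped.
    """
    if len(scores) != len(records):
        raise ValidationError("scores not aligned with records")
    logit = np.log(scores) - np.log1p(-scores)
    case_idx = [i for i, r in enumerate(records) if r.outcome == 1]
    ctrl_idx = [i for i, r in enumerate(records) if r.outcome == 0]
    caliper = caliper_sd * float(np.std(logit)) if len(logit) > 1 else np.inf
    if not ctrl_idx:
        logger.warning("matching: no control records available")
        return MatchedDataset([], case_idx, standardized_mean_differences(records),
                              {}, caliper)
    order = sorted(case_idx, key=lambda i: -scores[i])
    available = sorted(ctrl_idx, key=lambda i: logit[i])
    avail_logit = np.array([logit[i] for i in available])
    used = np.zeros(len(available), dtype=bool)
    pairs: list[tuple[int, int]] = []
    unmatched: list[int] = []
    for i in order:
        free = np.flatnonzero(~used)
        if len(free) == 0:
            unmatched.append(i)
            continue
        d = np.abs(avail_logit[free] - logit[i])
        k = int(np.argmin(d))
        if d[k] <= caliper:
            used[free[k]] = True
            pairs.append((i, available[free[k]]))
        else:
            unmatched.append(i)
    if unmatched:
        logger.info("matching: %d cases without an in-caliper control", len(unmatched))
    smd_before = standardized_mean_differences(records)
    matched = [i for pair in pairs for i in pair]
    smd_after = (
        standardized_mean_differences(records, np.array(matched)) if pairs else {}
    )
    return MatchedDataset(pairs, unmatched, smd_before, smd_after, caliper)


# ---------------------------------------------------------------------------
# stratified split


@dataclass
class SplitDataset:
    train: list[int]  # indices into the input records
    validation: list[int]
    fraction: float
    seed: int


def stratum_key(rec: CohortRecord) -> tuple:
    return (
        rec.outcome,
        rec.gestational_week,
        int(rec.duration_min // DURATION_BIN_MIN),
        rec.fetal_sex,
    )


def stratified_split(
    records: list[CohortRecord], fraction: float = 0.8, seed: int = 0
) -> SplitDataset:
    """Per-stratum split with largest-remainder rounding.

    The global training size is exactly round(fraction * N); strata are
    allocated floor(fraction * n_s) training slots, with the remaining slots
    given to the strata with the largest fractional remainders.  Singleton
    strata go to training with a warning.
    """
    if not records:
        raise ValidationError("no records to split")
    if not (0 < fraction < 1):
        raise ConfigError("split fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strata: dict[tuple, list[int]] = {}
    for i, rec in enumerate(records):
        strata.setdefault(stratum_key(rec), []).append(i)
    n = len(records)
    target_train = int(round(fraction * n))
    keys = sorted(strata.keys(), key=repr)
    quotas = np.array([fraction * len(strata[k]) for k in keys])
    base = np.floor(quotas).astype(int)
    short = target_train - base.sum()
    remainders = quotas - base
    order = np.lexsort((np.arange(len(keys)), -remainders))
    for j in order[: max(0, short)]:
        base[j] += 1
    train: list[int] = []
    validation: list[int] = []
    for k, quota in zip(keys, base):
        idx = list(strata[k])
        if len(idx) == 1 and quota == 0:
            logger.warning("singleton stratum %s assigned to training", k)
            quota = 1
        rng.shuffle(idx)
        train.extend(idx[:quota])
        validation.extend(idx[quota:])
    # singleton promotion can overshoot; rebalance from the largest strata
    while len(train) > target_train:
        donors = [k for k in keys if sum(1 for i in train if i in set(strata[k])) > 1]
        if not donors:
            break
        k = max(donors, key=lambda k: len(strata[k]))
        moved = next(i for i in reversed(train) if i in set(strata[k]))
        train.remove(moved)
        validation.append(moved)
    return SplitDataset(sorted(train), sorted(validation), fraction, seed)


# ---------------------------------------------------------------------------
# feature transformation


@dataclass
class TransformParams:
    """Per-feature normalisation rule with training-fitted parameters."""

    rules: dict[str, str]  # feature -> "zscore" | "minmax"
    params: dict[str, tuple[float, float]]  # (mean, sd) or (min, max)
    skewness: dict[str, float] = field(default_factory=dict)


def fit_transforms(
    train: pd.DataFrame, skew_threshold: float = SKEW_THRESHOLD
) -> TransformParams:
    """Choose and fit a normalisation per feature on training data only.

    Approximately symmetric features (|sample skewness| <= threshold) are
    z-scored; skewed features are min-max rescaled to [0, 1].
    """
    rules: dict[str, str] = {}
    params: dict[str, tuple[float, float]] = {}
    skews: dict[str, float] = {}
    for name in FeatureVector.FEATURE_NAMES:
        x = train[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValidationError(f"feature {name!r} is constant on the training data")
        s = float(skew(x))
        skews[name] = s
        if abs(s) > skew_threshold:
            rules[name] = "minmax"
            params[name] = (float(x.min()), float(x.max()))
        else:
            sd = float(x.std(ddof=0))
            rules[name] = "zscore"
            params[name] = (float(x.mean()), sd)
    return TransformParams(rules=rules, params=params, skewness=skews)


def apply_transforms(params: TransformParams, data: pd.DataFrame) -> pd.DataFrame:
    """Apply fitted transforms without re-estimating anything.

    Min-max outputs may leave [0, 1] outside the training data; they are
    logged, never clipped.
    """
    out = data.copy()
    for name, rule in params.rules.items():
        a, b = params.params[name]
        x = out[name].to_numpy(dtype=float)
        if rule == "zscore":
            out[name] = (x - a) / b
        else:
            y = (x - a) / (b - a)
            n_out = int(((y < 0) | (y > 1)).sum())
            if n_out:
                logger.info("min-max transform of %s: %d values outside [0, 1]",
                            name, n_out)
            out[name] = y
    return out
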