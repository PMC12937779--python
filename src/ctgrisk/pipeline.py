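"""End-to-end orchestration: simulate -> extract -> QC -> match -> split ->
transform -> train -> evaluate, as one seeded, logged run.

A single global seed fans out to per-stage seeds through a named
``numpy.random.SeedSequence`` derivation, so each stage is individually
reproducible.  The run writes a JSON master report, CSV tables (features,
QC, cross-validation) and a manifest with the seed, a config hash and
stage-wise record counts.

Following the matching convention of case-control studies where cases
outnumber controls, the analysis dataset keeps every case plus its matched
controls; controls without a match are dropped, unmatched cases are kept
and reported.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import metrics, models, qc
from .errors import ConfigError
from .features import FeatureVector, extract_features
from .simulate import FeatureTargets, SimulationConfig, simulate_cohort
from .trace_io import SUBTYPES, CohortRecord

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "split",
    "folds",
    "tuning",
    "final_fit",
    "bootstrap",
)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run; round-trips through YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc_thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "max_signal_loss_pct": qc.MAX_SIGNAL_LOSS_PCT,
            "min_basal_bpm": qc.MIN_BASAL_BPM,
            "max_basal_bpm": qc.MAX_BASAL_BPM,
            "max_accel_per_min": qc.MAX_ACCEL_PER_MIN,
            "max_most_lost_beats": qc.MAX_MOST_LOST_BEATS,
            "min_stv_ms": qc.MIN_STV_MS,
            "max_stv_ms": qc.MAX_STV_MS,
        }
    )
    max_days_before_delivery: float = qc.MAX_DAYS_BEFORE_DELIVERY
    caliper_sd: float = cohort_mod.DEFAULT_CALIPER_SD
    split_fraction: float = 0.8
    skew_threshold: float = cohort_mod.SKEW_THRESHOLD
    cv_folds: int = 10
    tuning_budget: int = 50
    families: tuple[str, ...] = models.MODEL_FAMILIES
    bootstrap_B: int = 1000
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        self.simulation.validate()
        if not (0 < self.split_fraction < 1):
            raise ConfigError("split fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.tuning_budget < 1:
            raise ConfigError("tuning budget must be >= 1")
        unknown = set(self.families) - set(models.MODEL_FAMILIES)
        if unknown:
            raise ConfigError(f"unknown model families {sorted(unknown)}")

    # -- YAML round-trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        sim = d["simulation"]
        sim["cohort_feature_targets"] = {
            c: {f: list(dataclasses.astuple(t)) for f, t in targets.items()}
            for c, targets in self.simulation.cohort_feature_targets.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "cohort_feature_targets" in sim:
            sim["cohort_feature_targets"] = {
                c: {f: FeatureTargets(*vals) for f, vals in targets.items()}
                for c, targets in sim["cohort_feature_targets"].items()
            }
        for key in ("gestation_range", "duration_minutes_range",
                    "signal_loss_fraction_range", "days_before_delivery_range",
                    "drift_bpm_range"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        d["simulation"] = SimulationConfig(**sim)
        if "families" in d:
            d["families"] = tuple(d["families"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def features_frame(records: list[CohortRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        if rec.features is None:
            raise ConfigError(f"record {rec.trace_id} lacks extracted features")
        row = {"trace_id": rec.trace_id, "cohort": rec.cohort,
               "gestational_age_days": rec.gestational_age_days,
               "gestational_week": rec.gestational_week,
               "fetal_sex": rec.fetal_sex, "duration_min": rec.duration_min,
               "outcome": rec.outcome}
        row.update(rec.features)
        for s in SUBTYPES:
            row[f"subtype_{s}"] = int(rec.subtypes.get(s, False))
        rows.append(row)
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute every stage in order and return the evaluation report."""
    config.validate()
    counts: dict[str, int] = {}
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # -- simulate -----------------------------------------------------------
    sim_cfg = dataclasses.replace(
        config.simulation, seed=stage_seed(config.seed, "simulate")
    )
    if sim_cfg.n_apo == 0 or sim_cfg.n_npo == 0:
        raise ConfigError("cohort stage requires records in both cohorts")
    traces, records, _truths = simulate_cohort(sim_cfg)
    counts["simulated"] = len(records)

    # -- extract ------------------------------------------------------------
    for trace, rec in zip(traces, records):
        fv = extract_features(trace)
        rec.features = fv.as_dict()
    counts["extracted"] = len(records)

    # -- QC -----------------------------------------------------------------
    qc_rows = []
    passed: list[CohortRecord] = []
    for rec in records:
        fv = FeatureVector(**{k: rec.features[k] for k in (
            *FeatureVector.FEATURE_NAMES, "analysed_duration_min", "signal_loss_pct")})
        result = qc.plausibility_filter(fv, rec.trace_id, **config.qc_thresholds)
        qc_rows.append({"trace_id": rec.trace_id, "passed": result.passed,
                        "failed_rules": ";".join(result.failed_rules)})
        if result.passed:
            passed.append(rec)
    counts["qc_passed"] = len(passed)
    passed = qc.first_trace_per_week(passed)
    counts["first_trace_per_week"] = len(passed)
    passed = qc.temporal_window_filter(passed, config.max_days_before_delivery)
    counts["temporal_window"] = len(passed)
    if not any(r.outcome == 1 for r in passed) or not any(r.outcome == 0 for r in passed):
        raise ConfigError("cohort stage failed: a cohort was filtered out entirely")

    # -- matching -----------------------------------------------------------
    scores = cohort_mod.estimate_propensity(passed)
    matched = cohort_mod.match_without_replacement(scores, passed, config.caliper_sd)
    keep_idx = sorted(
        {i for pair in matched.pairs for i in pair}
        | {i for i, r in enumerate(passed) if r.outcome == 1}
    )
    dataset = [passed[i] for i in keep_idx]
    counts["matched_dataset"] = len(dataset)

    # -- split and transform -------------------------------------------------
    split = cohort_mod.stratified_split(
        dataset, config.split_fraction, seed=stage_seed(config.seed, "split")
    )
    train_recs = [dataset[i] for i in split.train]
    valid_recs = [dataset[i] for i in split.validation]
    counts["train"], counts["validation"] = len(train_recs), len(valid_recs)
    train_df = features_frame(train_recs)
    valid_df = features_frame(valid_recs)
    params = cohort_mod.fit_transforms(train_df, config.skew_threshold)
    train_t = cohort_mod.apply_transforms(params, train_df)
    valid_t = cohort_mod.apply_transforms(params, valid_df)
    fnames = list(FeatureVector.FEATURE_NAMES)
    X_train = train_t[fnames].to_numpy(float)
    y_train = train_t["outcome"].to_numpy(int)
    X_valid = valid_t[fnames].to_numpy(float)
    y_valid = valid_t["outcome"].to_numpy(int)

    # -- cross-validated training and model comparison ----------------------
    fold_keys = [cohort_mod.stratum_key(r) for r in train_recs]
    folds = models.make_folds(fold_keys, k=config.cv_folds,
                              seed=stage_seed(config.seed, "folds"))
    cv_results: list[models.CVResult] = []
    tuned: dict[str, dict] = {}
    for family in config.families:
        spec = models.ModelSpec(family=family, seed=stage_seed(config.seed, f"model:{family}"))
        best, _log = models.tune(
            spec, X_train, y_train, folds,
            budget=config.tuning_budget,
            seed=stage_seed(config.seed, f"tune:{family}"),
        )
        tuned[family] = best
        cv_results.append(models.cross_validate(spec, X_train, y_train, folds, best))
        logger.info("tuned %s: mean CV AUC %.4f", family, cv_results[-1].mean_auc)
    comparison = models.compare_models(cv_results)
    best_family = max(cv_results, key=lambda r: r.mean_auc).family

    # -- final fit and evaluation -------------------------------------------
    spec = models.ModelSpec(family=best_family,
                            seed=stage_seed(config.seed, f"model:{best_family}"))
    final = models.fit_final(spec, X_train, y_train, tuned[best_family], folds)
    p_valid = final.predict_proba(X_valid)
    boot_seed = stage_seed(config.seed, "bootstrap")
    roc = metrics.roc_and_auc(p_valid, y_valid)
    auc_ci = (
        metrics.bootstrap_ci(metrics.rank_auc, p_valid, y_valid,
                             B=config.bootstrap_B, seed=boot_seed)
        if config.bootstrap_B else None
    )
    points = metrics.operating_points(
        p_valid, y_valid,
        bootstrap_B=min(config.bootstrap_B, 200) if config.bootstrap_B else 0,
        seed=boot_seed,
    )
    dcurve = metrics.decision_curve(p_valid, y_valid)
    weeks = valid_df["gestational_week"].to_numpy()
    per_week = metrics.stratified_auc(p_valid, y_valid, weeks)
    flags = valid_df[[f"subtype_{s}" for s in SUBTYPES]].rename(
        columns=lambda c: c.removeprefix("subtype_")
    )
    per_subtype = metrics.subtype_auc(p_valid, y_valid, flags)
    importances = (
        models.feature_importances(final, fnames)
        if best_family in models.ENSEMBLE_FAMILIES else None
    )
    full_df = features_frame(dataset)
    associations = metrics.feature_association_tests(
        full_df[fnames], full_df["outcome"].to_numpy(int), config.skew_threshold
    )

    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stage_counts": counts,
        "composition": qc.cohort_composition(dataset),
        "matching": {
            "pairs": len(matched.pairs),
            "unmatched_cases": len(matched.unmatched_cases),
            "caliper": matched.caliper,
            "smd_before": matched.smd_before,
            "smd_after": matched.smd_after,
        },
        "transforms": {"rules": params.rules, "skewness": params.skewness},
        "cv": {
            r.family: {"fold_aucs": r.fold_aucs, "mean_auc": r.mean_auc,
                       "median_auc": r.median_auc, "params": tuned[r.family]}
            for r in cv_results
        },
        "comparison": comparison,
        "best_family": best_family,
        "validation": {
            "auc": roc.auc,
            "auc_ci": auc_ci,
            "brier": metrics.brier(p_valid, y_valid),
            "operating_points": points,
            "decision_curve": {
                "thresholds": dcurve.thresholds,
                "net_benefit": dcurve.net_benefit,
                "treat_all": dcurve.treat_all,
                "dominates_treat_all": dcurve.dominates_treat_all,
                "dominates_treat_none": dcurve.dominates_treat_none,
            },
            "auc_by_gestational_week": per_week,
            "auc_by_subtype": per_subtype,
        },
        "feature_importances": importances,
        "feature_associations": associations.reset_index().to_dict("records"),
    }
    report = _jsonable(report)

    if out_dir:
        features_frame(dataset).to_csv(out_dir / "feature_table.csv", index=False)
        pd.DataFrame(qc_rows).to_csv(out_dir / "qc_report.csv", index=False)
        pd.DataFrame(
            [{"family": r.family, **{f"fold_{i}": a for i, a in enumerate(r.fold_aucs)}}
             for r in cv_results]
        ).to_csv(out_dir / "cv_table.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                    "stage_counts": counts,
                    "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES}}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        config.to_yaml(out_dir / "config.yaml")
    return report
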