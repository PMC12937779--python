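"""Plausibility filters and cohort-construction rules.

Traces with physiologically implausible or poor-quality features are
excluded: more than 30% signal loss, basal FHR below 100 or above 180 bpm,
more than 1 acceleration per analysed minute, more than 125 most lost beats,
or an STV below 2 or above 30 ms.  All inequalities are strict, so boundary
values are retained.

Cohort-construction rules: at most one trace per pregnancy per completed
gestational week (the earliest is kept), and adverse-outcome traces acquired
more than 7 days before delivery are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import ValidationError
from .features import FeatureVector
from .trace_io import CohortRecord

logger = logging.getLogger(__name__)

MAX_SIGNAL_LOSS_PCT = 30.0
MIN_BASAL_BPM = 100.0
MAX_BASAL_BPM = 180.0
MAX_ACCEL_PER_MIN = 1.0
MAX_MOST_LOST_BEATS = 125.0
MIN_STV_MS = 2.0
MAX_STV_MS = 30.0
MAX_DAYS_BEFORE_DELIVERY = 7.0


@dataclass
class QCResult:
    trace_id: str
    passed: bool
    failed_rules: list[str]

    def __post_init__(self) -> None:
        if self.passed != (not self.failed_rules):
            raise ValidationError("passed flag inconsistent with failed_rules")


def plausibility_filter(
    fv: FeatureVector,
    trace_id: str = "",
    *,
    max_signal_loss_pct: float = MAX_SIGNAL_LOSS_PCT,
    min_basal_bpm: float = MIN_BASAL_BPM,
    max_basal_bpm: float = MAX_BASAL_BPM,
    max_accel_per_min: float = MAX_ACCEL_PER_MIN,
    max_most_lost_beats: float = MAX_MOST_LOST_BEATS,
    min_stv_ms: float = MIN_STV_MS,
    max_stv_ms: float = MAX_STV_MS,
) -> QCResult:
    """Apply the plausibility rules to one feature vector.

    The acceleration-rate rule uses the analysed (<= 60 min) duration as its
    denominator, consistent with how the features themselves are computed.
    """
    failed: list[str] = []
    if fv.signal_loss_pct > max_signal_loss_pct:
        failed.append("signal_loss_gt_30pct")
    if fv.basal_fhr < min_basal_bpm or fv.basal_fhr > max_basal_bpm:
        failed.append("basal_fhr_outside_100_180")
    if fv.accelerations / fv.analysed_duration_min > max_accel_per_min:
        failed.append("accelerations_gt_1_per_min")
    if fv.most_lost_beats > max_most_lost_beats:
        failed.append("most_lost_beats_gt_125")
    if fv.stv < min_stv_ms or fv.stv > max_stv_ms:
        failed.append("stv_outside_2_30ms")
    if failed:
        logger.info("QC excluded %s: %s", trace_id or "<trace>", ",".join(failed))
    return QCResult(trace_id=trace_id, passed=not failed, failed_rules=failed)


def first_trace_per_week(records: list[CohortRecord]) -> list[CohortRecord]:
    """Keep at most one trace per pregnancy per completed gestational week.

    Within a (pregnancy, week) group the earliest acquisition (smallest
    gestational age in days, ties broken by trace id) is retained.
    """
    for rec in records:
        if rec.pregnancy_id is None or rec.gestational_age_days is None:
            raise ValidationError(f"record {rec.trace_id}: missing ordering key")
    best: dict[tuple[str, int], CohortRecord] = {}
    for rec in records:
        key = (rec.pregnancy_id, rec.gestational_week)
        cur = best.get(key)
        if cur is None or (rec.gestational_age_days, rec.trace_id) < (
            cur.gestational_age_days,
            cur.trace_id,
        ):
            if cur is not None:
                logger.info("repeat-trace rule excluded %s", cur.trace_id)
            best[key] = rec
    kept_ids = {id(rec) for rec in best.values()}
    return [rec for rec in records if id(rec) in kept_ids]


def temporal_window_filter(
    records: list[CohortRecord], max_days: float = MAX_DAYS_BEFORE_DELIVERY
) -> list[CohortRecord]:
    """Drop APO traces acquired more than ``max_days`` before delivery.

    Normal-outcome records are untouched; the inequality is strict, so a
    trace exactly ``max_days`` before delivery is retained.
    """
    kept = []
    for rec in records:
        if rec.cohort != "APO":
            kept.append(rec)
            continue
        if rec.days_before_delivery is None:
            raise ValidationError(
                f"record {rec.trace_id}: APO record lacks days_before_delivery"
            )
        if rec.days_before_delivery > max_days:
            logger.info("temporal-window rule excluded %s", rec.trace_id)
            continue
        kept.append(rec)
    return kept


def cohort_composition(records: list[CohortRecord]) -> dict[str, float]:
    """Cohort counts and composition percentages (one-decimal reporting)."""
    n = len(records)
    n_apo = sum(r.cohort == "APO" for r in records)
    n_male = sum(r.fetal_sex == "male" for r in records)
    return {
        "n": n,
        "n_npo": n - n_apo,
        "n_apo": n_apo,
        "n_male": n_male,
        "npo_pct": round(100.0 * (n - n_apo) / n, 1) if n else float("nan"),
        "apo_pct": round(100.0 * n_apo / n, 1) if n else float("nan"),
        "male_pct": round(100.0 * n_male / n, 1) if n else float("nan"),
    }
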