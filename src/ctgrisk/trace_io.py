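"""Reading and writing of FHR trace files and cohort tables.

Trace files use a small CSV dialect with columns ``time_s,fhr_bpm,missing``.
Missing samples carry an empty ``fhr_bpm`` field and ``missing=1``; in memory
they are NaN plus an explicit boolean mask.  Acquisition metadata travels in
``# key=value`` comment lines ahead of the header so that a trace file is
self-contained and round-trips losslessly.

Cohort tables are plain CSV with one row per trace carrying the covariates
(gestational age in days, fetal sex, trace duration), the outcome cohort
(``NPO``/``APO``), optional days-before-delivery, and ten binary adverse
outcome subtype columns.  All readers validate and reject rather than coerce.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: The ten adverse-outcome subtype labels an APO pregnancy can carry.
SUBTYPES = (
    "acidaemia",
    "stillbirth",
    "asphyxia",
    "birthweight_le_3rd",
    "extended_scbu",
    "hie",
    "low_apgar",
    "neonatal_sepsis",
    "perinatal_infection",
    "respiratory",
)

FETAL_SEXES = ("male", "female")
COHORTS = ("NPO", "APO")

_TRACE_COLUMNS = ["time_s", "fhr_bpm", "missing"]


@dataclass
class FHRTrace:
    """A time-stamped antepartum fetal heart rate recording.

    ``fhr_bpm`` is NaN wherever ``missing_mask`` is True; non-missing samples
    must be finite and strictly positive.  Time is 0-based seconds from trace
    start and strictly increasing; intervals are half-open ``[onset, offset)``.
    """

    trace_id: str
    time_s: np.ndarray
    fhr_bpm: np.ndarray
    missing_mask: np.ndarray
    sampling_rate: float
    pregnancy_id: str | None = None
    gestational_age_days: int | None = None
    fetal_sex: str | None = None
    duration_min: float | None = None
    days_before_delivery: float | None = None
    cohort: str | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fhr_bpm = np.asarray(self.fhr_bpm, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n = len(self.time_s)
        if not (len(self.fhr_bpm) == len(self.missing_mask) == n):
            raise ValidationError(
                f"trace {self.trace_id}: time/fhr/mask lengths differ "
                f"({n}/{len(self.fhr_bpm)}/{len(self.missing_mask)})"
            )
        if n == 0:
            raise ValidationError(f"trace {self.trace_id}: empty trace")
        if self.sampling_rate <= 0:
            raise ValidationError(f"trace {self.trace_id}: non-positive sampling rate")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValidationError(f"trace {self.trace_id}: time not strictly increasing")
        valid = ~self.missing_mask
        vals = self.fhr_bpm[valid]
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValidationError(
                f"trace {self.trace_id}: non-missing FHR must be finite and > 0"
            )
        if self.fetal_sex is not None and self.fetal_sex not in FETAL_SEXES:
            raise ValidationError(
                f"trace {self.trace_id}: unknown fetal_sex {self.fetal_sex!r}"
            )
        if self.cohort is not None and self.cohort not in COHORTS:
            raise ValidationError(f"trace {self.trace_id}: unknown cohort {self.cohort!r}")
        span_min = (self.time_s[-1] - self.time_s[0] + 1.0 / self.sampling_rate) / 60.0
        if self.duration_min is None:
            self.duration_min = span_min
        elif abs(self.duration_min - span_min) > 1.0 / self.sampling_rate / 60.0 + 1e-9:
            raise ValidationError(
                f"trace {self.trace_id}: duration_min {self.duration_min:.4f} "
                f"inconsistent with timestamps ({span_min:.4f})"
            )

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate


@dataclass
class CohortRecord:
    """Per-trace covariates, outcome label and subtype flags.

    ``features`` is filled in after extraction (a mapping of the seven feature
    names plus analysed duration and signal loss) and is None beforehand.
    """

    trace_id: str
    pregnancy_id: str
    cohort: str
    gestational_age_days: int
    fetal_sex: str
    duration_min: float
    days_before_delivery: float | None = None
    subtypes: dict[str, bool] = field(default_factory=dict)
    features: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(f"record {self.trace_id}: unknown cohort {self.cohort!r}")
        if self.fetal_sex not in FETAL_SEXES:
            raise ValidationError(
                f"record {self.trace_id}: unknown fetal_sex {self.fetal_sex!r}"
            )
        if self.gestational_age_days is None or (
            isinstance(self.gestational_age_days, float)
            and math.isnan(self.gestational_age_days)
        ):
            raise ValidationError(f"record {self.trace_id}: missing gestational age")
        self.gestational_age_days = int(self.gestational_age_days)
        if not self.duration_min > 0:
            raise ValidationError(f"record {self.trace_id}: non-positive duration")
        unknown = set(self.subtypes) - set(SUBTYPES)
        if unknown:
            raise ValidationError(f"record {self.trace_id}: unknown subtypes {sorted(unknown)}")
        if self.cohort == "APO" and not any(self.subtypes.get(s, False) for s in SUBTYPES):
            raise ValidationError(
                f"record {self.trace_id}: APO record must carry at least one subtype"
            )

    @property
    def outcome(self) -> int:
        """Binary outcome label: 1 for APO, 0 for NPO."""
        return 1 if self.cohort == "APO" else 0

    @property
    def gestational_week(self) -> int:
        """Completed gestational weeks at acquisition."""
        return self.gestational_age_days // 7


def weeks_days_to_days(weeks: int, days: int) -> int:
    """Convert obstetric ``weeks+days`` notation (e.g. 27+0) to days."""
    if not (0 <= days <= 6):
        raise ValidationError(f"days part must be in 0..6, got {days}")
    return 7 * weeks + days


# ---------------------------------------------------------------------------
# trace files


def write_trace(trace: FHRTrace, path: str | Path) -> None:
    """Write a trace in the ``time_s,fhr_bpm,missing`` dialect."""
    path = Path(path)
    meta: dict[str, object] = {
        "trace_id": trace.trace_id,
        "sampling_rate": trace.sampling_rate,
    }
    for key in (
        "pregnancy_id",
        "gestational_age_days",
        "fetal_sex",
        "duration_min",
        "days_before_delivery",
        "cohort",
    ):
        val = getattr(trace, key)
        if val is not None:
            meta[key] = val
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write(",".join(_TRACE_COLUMNS) + "\n")
        for t, v, m in zip(trace.time_s, trace.fhr_bpm, trace.missing_mask):
            sval = "" if m else format(v, ".17g")
            fh.write(f"{t:.6f},{sval},{int(m)}\n")


def read_trace(path: str | Path) -> FHRTrace:
    """Read a trace file, validating the dialect and all invariants."""
    path = Path(path)
    meta: dict[str, str] = {}
    header_line = None
    rows: list[tuple[float, float, bool]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if header_line is None:
                cols = [c.strip() for c in line.split(",")]
                if cols != _TRACE_COLUMNS:
                    raise ParseError(
                        f"{path}:{lineno}: expected header "
                        f"{','.join(_TRACE_COLUMNS)!r}, got {line!r}"
                    )
                header_line = lineno
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                t = float(parts[0])
                missing = bool(int(parts[2]))
                v = math.nan if parts[1] == "" else float(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if missing and parts[1] != "":
                raise ParseError(f"{path}:{lineno}: missing sample carries a value")
            if not missing and parts[1] == "":
                raise ParseError(f"{path}:{lineno}: non-missing sample lacks a value")
            rows.append((t, v, missing))
    if header_line is None or not rows:
        raise ParseError(f"{path}: no samples found")
    if "sampling_rate" not in meta:
        raise ParseError(f"{path}: missing '# sampling_rate=' metadata")
    time_s = np.array([r[0] for r in rows])
    fhr = np.array([r[1] for r in rows])
    mask = np.array([r[2] for r in rows])
    kwargs: dict[str, object] = {}
    if "gestational_age_days" in meta:
        kwargs["gestational_age_days"] = int(float(meta["gestational_age_days"]))
    for key in ("pregnancy_id", "fetal_sex", "cohort"):
        if key in meta:
            kwargs[key] = meta[key]
    for key in ("duration_min", "days_before_delivery"):
        if key in meta:
            kwargs[key] = float(meta[key])
    try:
        return FHRTrace(
            trace_id=meta.get("trace_id", path.stem),
            time_s=time_s,
            fhr_bpm=fhr,
            missing_mask=mask,
            sampling_rate=float(meta["sampling_rate"]),
            **kwargs,
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# cohort tables


def _records_frame(records: list[CohortRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rec.validate()  # records may have been mutated since construction
        row: dict[str, object] = {
            "trace_id": rec.trace_id,
            "pregnancy_id": rec.pregnancy_id,
            "cohort": rec.cohort,
            "gestational_age_days": rec.gestational_age_days,
            "fetal_sex": rec.fetal_sex,
            "duration_min": rec.duration_min,
            "days_before_delivery": rec.days_before_delivery,
        }
        for s in SUBTYPES:
            row[f"subtype_{s}"] = int(rec.subtypes.get(s, False))
        rows.append(row)
    cols = [
        "trace_id",
        "pregnancy_id",
        "cohort",
        "gestational_age_days",
        "fetal_sex",
        "duration_min",
        "days_before_delivery",
    ] + [f"subtype_{s}" for s in SUBTYPES]
    return pd.DataFrame(rows, columns=cols)


def write_cohort_table(records: list[CohortRecord], path: str | Path) -> None:
    _records_frame(records).to_csv(path, index=False)


def read_cohort_table(path: str | Path) -> list[CohortRecord]:
    df = pd.read_csv(path, dtype={"trace_id": str, "pregnancy_id": str})
    required = {"trace_id", "pregnancy_id", "cohort", "gestational_age_days",
                "fetal_sex", "duration_min"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing columns {sorted(missing_cols)}")
    records = []
    for i, row in df.iterrows():
        if pd.isna(row["cohort"]):
            raise ValidationError(f"{path}: row {i + 2}: missing outcome label")
        subtypes = {}
        for s in SUBTYPES:
            col = f"subtype_{s}"
            if col in df.columns and not pd.isna(row[col]):
                subtypes[s] = bool(int(row[col]))
        dbd = row.get("days_before_delivery")
        try:
            records.append(
                CohortRecord(
                    trace_id=str(row["trace_id"]),
                    pregnancy_id=str(row["pregnancy_id"]),
                    cohort=str(row["cohort"]),
                    gestational_age_days=row["gestational_age_days"],
                    fetal_sex=str(row["fetal_sex"]),
                    duration_min=float(row["duration_min"]),
                    days_before_delivery=None if pd.isna(dbd) else float(dbd),
                    subtypes=subtypes,
                )
            )
        except (ValidationError, TypeError) as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from None
    return records


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(rows: list[tuple[str, object]], path: str | Path) -> None:
    """Write per-trace feature vectors (``(trace_id, FeatureVector)`` pairs)."""
    out = []
    for trace_id, fv in rows:
        d = dataclasses.asdict(fv)
        d = {"trace_id": trace_id, **d}
        out.append(d)
    pd.DataFrame(out).to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"trace_id": str})
    if "trace_id" not in df.columns:
        raise ParseError(f"{path}: missing trace_id column")
    return df
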