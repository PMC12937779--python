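"""Seven-feature extraction from antepartum FHR traces.

The features follow the Dawes–Redman family of computerised cardiotocography
measures: basal FHR, acceleration and deceleration counts, most lost beats,
short-term variation (STV), and minutes spent in episodes of high and low
variation.  Features are extracted from at most the first 60 minutes of a
trace.

Definitions
-----------
baseline
    The average FHR excluding major deviations, estimated by an iterative
    trimmed moving average (10-minute window; samples deviating more than
    10 bpm from the current estimate are excluded; iterated to convergence).
acceleration
    A maximal run of samples at least 10 bpm above baseline lasting longer
    than 15 s.
deceleration
    A maximal run of samples at least 10 bpm below baseline that either
    sustains a 20 bpm drop for longer than 30 s or lasts longer than 60 s.
lost beats
    The integrated area of a deceleration below baseline (depth in bpm times
    duration in minutes); for a rectangular deceleration this equals the
    duration-times-magnitude product.  Most lost beats (MLB) is the largest
    such loss in a trace.
STV
    Pulse intervals (60000/FHR, ms) are averaged on 3.75 s epochs (16 per
    minute); STV is the mean absolute difference between successive valid
    epoch means.  Epochs overlapping detected events or dominated by missing
    samples are excluded.
variation episodes
    Each minute is classified by the range of its epoch pulse intervals:
    at or above 32 ms qualifies as high variation, at or below 30 ms as low
    variation.  An episode requires at least 5 qualifying minutes in any
    6-minute window; qualifying minutes covered by such a window count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import ExtractionError, ValidationError
from .trace_io import FHRTrace

# Detection thresholds (bpm / seconds); strict inequalities on duration.
ACCEL_AMPLITUDE_BPM = 10.0
ACCEL_MIN_DURATION_S = 15.0
DECEL_AMPLITUDE_BPM = 10.0
DECEL_DEEP_AMPLITUDE_BPM = 20.0
DECEL_DEEP_MIN_DURATION_S = 30.0
DECEL_MIN_DURATION_S = 60.0
EVENT_BRIDGE_GAP_S = 5.0

# Baseline estimation.
BASELINE_WINDOW_MIN = 10.0
BASELINE_TRIM_BPM = 10.0
BASELINE_TOL_BPM = 0.1
BASELINE_MAX_ITER = 20

# STV / variation episodes.
EPOCH_S = 3.75
EPOCHS_PER_MIN = 16
HIGH_VARIATION_RANGE_MS = 32.0
LOW_VARIATION_RANGE_MS = 30.0
EPISODE_WINDOW_MIN = 6
EPISODE_MIN_QUALIFYING = 5
MINUTE_MAX_MISSING_FRACTION = 0.5
MINUTE_MIN_VALID_EPOCHS = 8

ANALYSIS_CAP_MIN = 60.0


@dataclass
class Baseline:
    """Per-sample baseline estimate aligned with a trace."""

    baseline_bpm: np.ndarray


@dataclass
class FHREvent:
    """A detected acceleration or deceleration."""

    kind: str  # "acceleration" | "deceleration"
    onset_s: float
    offset_s: float
    peak_deviation_bpm: float
    lost_beats: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("acceleration", "deceleration"):
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if not self.offset_s > self.onset_s:
            raise ValidationError("event offset must exceed onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class FeatureVector:
    """The seven per-trace FHR features plus bookkeeping fields."""

    basal_fhr: float
    accelerations: int
    decelerations: int
    most_lost_beats: float
    stv: float
    high_variation_min: float
    low_variation_min: float
    analysed_duration_min: float
    signal_loss_pct: float

    FEATURE_NAMES = (
        "basal_fhr",
        "accelerations",
        "decelerations",
        "most_lost_beats",
        "stv",
        "high_variation_min",
        "low_variation_min",
    )

    def __post_init__(self) -> None:
        if self.accelerations < 0 or self.decelerations < 0:
            raise ValidationError("event counts must be non-negative")
        if self.most_lost_beats < 0 or self.stv < 0:
            raise ValidationError("MLB and STV must be non-negative")
        if (self.most_lost_beats == 0) != (self.decelerations == 0):
            raise ValidationError("most_lost_beats must be 0 iff there are no decelerations")
        if self.analysed_duration_min > ANALYSIS_CAP_MIN + 1e-9:
            raise ValidationError("analysed duration exceeds the 60-minute cap")
        for name in ("high_variation_min", "low_variation_min"):
            v = getattr(self, name)
            if v < 0 or v > self.analysed_duration_min + 1e-9:
                raise ValidationError(f"{name} outside [0, analysed duration]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FEATURE_NAMES} | {
            "analysed_duration_min": self.analysed_duration_min,
            "signal_loss_pct": self.signal_loss_pct,
        }


# ---------------------------------------------------------------------------
# baseline


def fit_baseline(
    trace: FHRTrace,
    window_min: float = BASELINE_WINDOW_MIN,
    trim_bpm: float = BASELINE_TRIM_BPM,
    tol_bpm: float = BASELINE_TOL_BPM,
    max_iter: int = BASELINE_MAX_ITER,
) -> Baseline:
    """Iterative trimmed moving average; robust to transient deviations.

    Samples deviating more than ``trim_bpm`` from the current estimate are
    excluded from the windowed mean, so a planted 60 s / 30 bpm deceleration
    moves the estimate by well under 2 bpm anywhere.
    """
    valid = ~trace.missing_mask
    if valid.sum() * trace.dt < 60.0:
        raise ExtractionError(
            f"trace {trace.trace_id}: fewer than one minute of usable signal"
        )
    fhr = np.where(valid, trace.fhr_bpm, 0.0)
    window = max(3, int(round(window_min * 60.0 * trace.sampling_rate)))
    est = np.full(len(trace), float(np.median(trace.fhr_bpm[valid])))
    for _ in range(max_iter):
        include = valid & (np.abs(trace.fhr_bpm - est) <= trim_bpm)
        if not include.any():
            break
        num = uniform_filter1d(np.where(include, fhr, 0.0), window, mode="constant")
        den = uniform_filter1d(include.astype(float), window, mode="constant")
        with np.errstate(invalid="ignore"):
            new = num / den
        bad = ~np.isfinite(new)
        if bad.any():
            fill = float(fhr[include].sum() / include.sum())
            new[bad] = fill
        if np.max(np.abs(new - est)) < tol_bpm:
            est = new
            break
        est = new
    return Baseline(baseline_bpm=est)


# ---------------------------------------------------------------------------
# events


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, stop) index pairs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_runs(
    runs: list[tuple[int, int]], time_s: np.ndarray, dt: float, bridge_s: float
) -> list[tuple[int, int]]:
    """Merge runs separated by less than ``bridge_s`` of sub-threshold signal."""
    if not runs:
        return []
    merged = [runs[0]]
    for start, stop in runs[1:]:
        prev_start, prev_stop = merged[-1]
        gap = time_s[start] - (time_s[prev_stop] + dt)
        if gap < bridge_s:
            merged[-1] = (prev_start, stop)
        else:
            merged.append((start, stop))
    return merged


def _run_duration(run: tuple[int, int], time_s: np.ndarray, dt: float) -> float:
    start, stop = run
    return time_s[stop] + dt - time_s[start]


def lost_beats(event: FHREvent, trace: FHRTrace, baseline: Baseline) -> float:
    """Integrated area of a deceleration below baseline, in beats.

    Equals depth (bpm) x duration (minutes) summed over the event; for a
    rectangular deceleration this is the plain duration-times-magnitude
    product.
    """
    if event.kind != "deceleration":
        raise ValidationError("lost_beats is defined for decelerations only")
    sel = (trace.time_s >= event.onset_s) & (trace.time_s < event.offset_s)
    sel &= ~trace.missing_mask
    depth = baseline.baseline_bpm[sel] - trace.fhr_bpm[sel]
    depth = np.clip(depth, 0.0, None)
    return float(depth.sum() * trace.dt / 60.0)


def detect_events(trace: FHRTrace, baseline: Baseline) -> list[FHREvent]:
    """Detect accelerations and decelerations against a fitted baseline.

    Runs of qualifying deviation separated by less than 5 s are bridged, so
    sampling noise does not split a single physiological event.  Durations
    use the half-open convention (offset = last sample time + dt), and the
    duration thresholds are strict.
    """
    dev = trace.fhr_bpm - baseline.baseline_bpm
    valid = ~trace.missing_mask
    dt, time_s = trace.dt, trace.time_s
    events: list[FHREvent] = []

    accel_mask = valid & (dev >= ACCEL_AMPLITUDE_BPM)
    for run in _merge_runs(_bool_runs(accel_mask), time_s, dt, EVENT_BRIDGE_GAP_S):
        if _run_duration(run, time_s, dt) > ACCEL_MIN_DURATION_S:
            i0, i1 = run
            seg = np.where(valid[i0 : i1 + 1], dev[i0 : i1 + 1], 0.0)
            events.append(
                FHREvent(
                    kind="acceleration",
                    onset_s=float(time_s[i0]),
                    offset_s=float(time_s[i1] + dt),
                    peak_deviation_bpm=float(seg.max()),
                )
            )

    decel_mask = valid & (dev <= -DECEL_AMPLITUDE_BPM)
    for run in _merge_runs(_bool_runs(decel_mask), time_s, dt, EVENT_BRIDGE_GAP_S):
        i0, i1 = run
        duration = _run_duration(run, time_s, dt)
        qualifies = duration > DECEL_MIN_DURATION_S
        if not qualifies:
            deep = valid[i0 : i1 + 1] & (dev[i0 : i1 + 1] <= -DECEL_DEEP_AMPLITUDE_BPM)
            for deep_run in _bool_runs(deep):
                d0, d1 = deep_run[0] + i0, deep_run[1] + i0
                if _run_duration((d0, d1), time_s, dt) > DECEL_DEEP_MIN_DURATION_S:
                    qualifies = True
                    break
        if qualifies:
            seg = np.where(valid[i0 : i1 + 1], dev[i0 : i1 + 1], 0.0)
            ev = FHREvent(
                kind="deceleration",
                onset_s=float(time_s[i0]),
                offset_s=float(time_s[i1] + dt),
                peak_deviation_bpm=float(seg.min()),
            )
            ev.lost_beats = lost_beats(ev, trace, baseline)
            events.append(ev)

    events.sort(key=lambda e: e.onset_s)
    return events


def most_lost_beats(events: list[FHREvent]) -> float:
    """Largest loss of beats over all decelerations; 0 when there are none."""
    losses = [e.lost_beats for e in events if e.kind == "deceleration"]
    return float(max(losses)) if losses else 0.0


# ---------------------------------------------------------------------------
# STV and variation episodes


def _epoch_values(
    trace: FHRTrace, events: list[FHREvent]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean pulse interval (ms) per 3.75 s epoch, with validity/event masks.

    Samples inside detected events are excluded (transient deviations are not
    variability), as are epochs with more than half their samples missing and
    epochs inside minutes with more than half their samples missing.  The
    third return flags epochs touched by an event at all, used to disqualify
    their minutes from variation-episode classification.
    """
    t0 = trace.time_s[0]
    rel = trace.time_s - t0
    n_epochs = int(np.floor((rel[-1] + trace.dt) / EPOCH_S + 1e-9))
    if n_epochs < 1:
        return np.zeros(0), np.zeros(0, dtype=bool)
    epoch_idx = np.minimum((rel / EPOCH_S).astype(int), n_epochs - 1)
    keep = rel < n_epochs * EPOCH_S - 1e-9

    usable = ~trace.missing_mask
    in_event = np.zeros(len(trace), dtype=bool)
    for ev in events:
        in_event |= (trace.time_s >= ev.onset_s) & (trace.time_s < ev.offset_s)
    sample_ok = usable & ~in_event & keep

    epoch_has_event = np.bincount(
        epoch_idx[keep & in_event], minlength=n_epochs
    ) > 0
    expected = np.bincount(epoch_idx[keep], minlength=n_epochs)
    n_ok = np.bincount(epoch_idx[sample_ok], minlength=n_epochs)
    with np.errstate(divide="ignore", invalid="ignore"):
        pulse = np.where(usable, 60000.0 / trace.fhr_bpm, 0.0)
    sums = np.bincount(epoch_idx[sample_ok], weights=pulse[sample_ok], minlength=n_epochs)
    values = np.full(n_epochs, np.nan)
    good = n_ok > 0
    values[good] = sums[good] / n_ok[good]
    epoch_valid = good & (n_ok >= np.maximum(1, expected // 2 + expected % 2))

    # minute-level missingness guard
    n_minutes = n_epochs // EPOCHS_PER_MIN
    if n_minutes > 0:
        minute_idx = np.minimum(epoch_idx // EPOCHS_PER_MIN, n_minutes - 1)
        in_minute = keep & (epoch_idx < n_minutes * EPOCHS_PER_MIN)
        per_min_total = np.bincount(minute_idx[in_minute], minlength=n_minutes)
        per_min_missing = np.bincount(
            minute_idx[in_minute & trace.missing_mask], minlength=n_minutes
        )
        with np.errstate(invalid="ignore"):
            frac = np.where(per_min_total > 0, per_min_missing / per_min_total, 1.0)
        bad_minutes = frac > MINUTE_MAX_MISSING_FRACTION
        if bad_minutes.any():
            epoch_minute = np.arange(n_epochs) // EPOCHS_PER_MIN
            in_range = epoch_minute < n_minutes
            mask = np.zeros(n_epochs, dtype=bool)
            mask[in_range] = bad_minutes[epoch_minute[in_range]]
            epoch_valid &= ~mask
    return values, epoch_valid, epoch_has_event


def compute_stv(trace: FHRTrace, events: list[FHREvent] | None = None) -> float:
    """Short-term variation: mean |successive difference| of epoch pulse
    intervals (ms) over valid, non-missing, non-event epochs."""
    if events is None:
        events = detect_events(trace, fit_baseline(trace))
    values, valid, _ = _epoch_values(trace, events)
    pair_ok = valid[:-1] & valid[1:]
    if pair_ok.sum() < 1:
        raise ExtractionError(
            f"trace {trace.trace_id}: insufficient valid epochs for STV"
        )
    diffs = np.abs(np.diff(values))
    return float(diffs[pair_ok].mean())


def _qualifying_minutes(
    values: np.ndarray, valid: np.ndarray, has_event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute high/low qualification from epoch pulse-interval ranges.

    Minutes overlapping a detected event are not classified: episodes
    describe the variability of the signal between transient events, and a
    partially event-covered minute would otherwise be judged on a truncated
    sample of epochs.
    """
    n_minutes = len(values) // EPOCHS_PER_MIN
    high = np.zeros(n_minutes, dtype=bool)
    low = np.zeros(n_minutes, dtype=bool)
    for m in range(n_minutes):
        sl = slice(m * EPOCHS_PER_MIN, (m + 1) * EPOCHS_PER_MIN)
        v, ok = values[sl], valid[sl]
        if has_event[sl].any() or ok.sum() < MINUTE_MIN_VALID_EPOCHS:
            continue
        rng = float(v[ok].max() - v[ok].min())
        if rng >= HIGH_VARIATION_RANGE_MS:
            high[m] = True
        elif rng <= LOW_VARIATION_RANGE_MS:
            low[m] = True
    return high, low


def _episode_minutes(qualifying: np.ndarray) -> float:
    """Minutes inside episodes: qualifying minutes covered by a 6-minute
    window containing at least 5 qualifying minutes."""
    n = len(qualifying)
    if n < EPISODE_WINDOW_MIN:
        return 0.0
    counted = np.zeros(n, dtype=bool)
    counts = np.convolve(qualifying.astype(int), np.ones(EPISODE_WINDOW_MIN, dtype=int),
                         mode="valid")
    for start in np.flatnonzero(counts >= EPISODE_MIN_QUALIFYING):
        sl = slice(start, start + EPISODE_WINDOW_MIN)
        counted[sl] |= qualifying[sl]
    return float(counted.sum())


def variation_episodes(
    trace: FHRTrace, events: list[FHREvent] | None = None
) -> tuple[float, float]:
    """Minutes spent in high- and low-variation episodes."""
    if events is None:
        events = detect_events(trace, fit_baseline(trace))
    values, valid, has_event = _epoch_values(trace, events)
    high_q, low_q = _qualifying_minutes(values, valid, has_event)
    return _episode_minutes(high_q), _episode_minutes(low_q)


# ---------------------------------------------------------------------------
# full extraction


def truncate_trace(trace: FHRTrace, cap_min: float = ANALYSIS_CAP_MIN) -> FHRTrace:
    """Restrict a trace to its first ``cap_min`` minutes."""
    horizon = trace.time_s[0] + cap_min * 60.0
    keep = trace.time_s < horizon - 1e-9
    if keep.all():
        return trace
    return FHRTrace(
        trace_id=trace.trace_id,
        time_s=trace.time_s[keep],
        fhr_bpm=trace.fhr_bpm[keep],
        missing_mask=trace.missing_mask[keep],
        sampling_rate=trace.sampling_rate,
        pregnancy_id=trace.pregnancy_id,
        gestational_age_days=trace.gestational_age_days,
        fetal_sex=trace.fetal_sex,
        days_before_delivery=trace.days_before_delivery,
        cohort=trace.cohort,
    )


def extract_features(trace: FHRTrace) -> FeatureVector:
    """Extract the seven FHR features from the first <= 60 minutes."""
    window = truncate_trace(trace)
    if window.missing_mask.all():
        raise ExtractionError(f"trace {trace.trace_id}: all samples missing")
    baseline = fit_baseline(window)
    events = detect_events(window, baseline)
    accels = [e for e in events if e.kind == "acceleration"]
    decels = [e for e in events if e.kind == "deceleration"]
    stv = compute_stv(window, events)
    high_min, low_min = variation_episodes(window, events)
    analysed_min = (window.time_s[-1] + window.dt - window.time_s[0]) / 60.0
    return FeatureVector(
        basal_fhr=float(baseline.baseline_bpm.mean()),
        accelerations=len(accels),
        decelerations=len(decels),
        most_lost_beats=most_lost_beats(events),
        stv=stv,
        high_variation_min=high_min,
        low_variation_min=low_min,
        analysed_duration_min=float(analysed_min),
        signal_loss_pct=float(window.missing_mask.mean() * 100.0),
    )
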