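"""Synthetic FHR trace and cohort generation with planted ground truth.

The generator works backwards from the seven extracted features: for each
trace it draws target feature values from per-cohort distributions (defaults
calibrated to the reported normal-outcome vs preterm-adverse-outcome group
differences), then constructs a signal that realises them:

* a piecewise-constant-plus-drift baseline in beats per minute;
* beat-to-beat variability generated on the pulse-interval scale
  (interval = 60000/FHR, ms) as a bounded zigzag walk whose step size equals
  the target short-term variation and whose per-minute excursion band is set
  by the planted variation regime (high episode / low episode / neutral);
* trapezoidal accelerations and decelerations whose amplitudes and durations
  strictly exceed the detection thresholds by a safety margin;
* whole-minute signal-loss blackouts recorded in the planted truth.

Because the walk lands exactly on its band walls, the per-minute range of
epoch pulse intervals is controlled to within the epoch jitter, so minutes
classify deterministically as high variation (range >= 32 ms), low variation
(range <= 30 ms) or neutral (band pinned just above 30 ms), and extraction
recovers the planted episode minutes and event counts exactly under default
noise margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, ValidationError
from .features import EPOCH_S, FeatureVector
from .trace_io import (
    COHORTS,
    SUBTYPES,
    CohortRecord,
    FHRTrace,
    write_cohort_table,
    write_trace,
)

FEATURES = FeatureVector.FEATURE_NAMES


@dataclass(frozen=True)
class FeatureTargets:
    """Quartile targets (and optional tail bounds) for one feature."""

    q1: float
    median: float
    q3: float
    lo: float | None = None
    hi: float | None = None

    def knots(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.lo if self.lo is not None else max(0.0, self.q1 - 1.5 * (self.median - self.q1))
        hi = self.hi if self.hi is not None else self.q3 + 2.0 * (self.q3 - self.median)
        ys = np.maximum.accumulate([lo, self.q1, self.median, self.q3, hi])
        return np.array([0.0, 0.25, 0.5, 0.75, 1.0]), ys


# Defaults follow the published group medians/IQRs where those are feasible
# under the extraction conventions.  Most-lost-beats targets are conditional
# on having at least one deceleration and sit at the feasible floor implied
# by the detection criteria (a qualifying deceleration loses >= ~13 beats);
# episode-time targets respect the 5-of-6-minute episode persistence rule
# (any nonzero per-trace episode time is >= 5 min).
DEFAULT_TARGETS: dict[str, dict[str, FeatureTargets]] = {
    "NPO": {
        "basal_fhr": FeatureTargets(132, 138, 144, lo=124, hi=146),
        "accelerations": FeatureTargets(3, 5, 8, lo=0, hi=12),
        "decelerations": FeatureTargets(0, 0, 1, lo=0, hi=2),
        "most_lost_beats": FeatureTargets(13.8, 15, 18, lo=13.8, hi=26),
        "stv": FeatureTargets(8, 9, 11, lo=6, hi=14),
        "high_variation_min": FeatureTargets(3, 7, 14, lo=0, hi=22),
        "low_variation_min": FeatureTargets(0, 0, 1, lo=0, hi=6),
    },
    "APO": {
        "basal_fhr": FeatureTargets(132, 139, 145, lo=128, hi=148),
        "accelerations": FeatureTargets(1, 3, 5, lo=0, hi=9),
        "decelerations": FeatureTargets(0, 0, 1, lo=0, hi=3.5),
        "most_lost_beats": FeatureTargets(15, 19, 30, lo=13.8, hi=50),
        "stv": FeatureTargets(5, 7, 9, lo=4.2, hi=13),
        "high_variation_min": FeatureTargets(0, 0, 7, lo=0, hi=12),
        "low_variation_min": FeatureTargets(0, 5, 22, lo=0, hi=35),
    },
}

#: Features whose medians are higher in the normal-outcome cohort; the
#: remaining four run higher in the adverse-outcome cohort.
NPO_HIGHER = ("accelerations", "high_variation_min", "stv")
APO_HIGHER = ("basal_fhr", "decelerations", "low_variation_min", "most_lost_beats")

DEFAULT_SUBTYPE_PREVALENCES: dict[str, float] = {
    "low_apgar": 0.22,
    "extended_scbu": 0.30,
    "birthweight_le_3rd": 0.25,
    "respiratory": 0.20,
    "acidaemia": 0.15,
    "neonatal_sepsis": 0.10,
    "perinatal_infection": 0.08,
    "asphyxia": 0.05,
    "stillbirth": 0.04,
    "hie": 0.02,
}


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohorts.

    Gestational ages span 27+0 to 36+6 weeks (189-258 days); sampling rate
    defaults to 4 Hz, the standard cardiotocograph output rate.
    """

    n_npo: int = 500
    n_apo: int = 500
    gestation_range: tuple[int, int] = (189, 258)
    duration_minutes_range: tuple[int, int] = (30, 75)
    sampling_rate: float = 4.0
    seed: int = 0
    cohort_feature_targets: dict[str, dict[str, FeatureTargets]] = field(
        default_factory=lambda: {c: dict(DEFAULT_TARGETS[c]) for c in COHORTS}
    )
    signal_loss_fraction_range: tuple[float, float] = (0.02, 0.15)
    subtype_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_PREVALENCES)
    )
    subtype_correlation: float = 0.3
    male_fraction: float = 0.488
    days_before_delivery_range: tuple[int, int] = (0, 7)
    drift_bpm_range: tuple[float, float] = (-2.0, 2.0)
    epoch_jitter_ms: float = 0.15
    sample_noise_ms: float = 0.3
    event_margin_bpm: float = 4.0
    event_margin_s: float = 5.0

    def validate(self) -> None:
        if self.n_npo < 0 or self.n_apo < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling rate must be positive")
        lo, hi = self.gestation_range
        if not (189 <= lo <= hi <= 258):
            raise ConfigError("gestation bounds must lie within [189, 258] days")
        dlo, dhi = self.duration_minutes_range
        if dlo <= 0 or dhi < dlo:
            raise ConfigError("duration range must be positive and ordered")
        flo, fhi = self.signal_loss_fraction_range
        if not (0 <= flo <= fhi < 1):
            raise ConfigError("signal loss fractions must lie in [0, 1)")
        for name, p in self.subtype_prevalences.items():
            if name not in SUBTYPES:
                raise ConfigError(f"unknown subtype {name!r}")
            if not (0 <= p <= 1):
                raise ConfigError(f"subtype prevalence for {name} outside [0, 1]")
        for cohort, targets in self.cohort_feature_targets.items():
            if cohort not in COHORTS:
                raise ConfigError(f"unknown cohort {cohort!r}")
            for fname, t in targets.items():
                if fname not in FEATURES:
                    raise ConfigError(f"unknown feature {fname!r}")
                if t.median < 0 or t.q1 < 0 or t.q3 < t.q1:
                    raise ConfigError(f"infeasible targets for {fname}: {t}")


def _sample_target(rng: np.random.Generator, t: FeatureTargets) -> float:
    xs, ys = t.knots()
    return float(np.interp(rng.random(), xs, ys))


# ---------------------------------------------------------------------------
# trace planning


@dataclass
class PlannedEvent:
    kind: str
    onset_s: float
    duration_s: float
    amplitude_bpm: float  # signed: accelerations positive, decelerations negative
    ramp_s: float = 2.0

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def lost_beats(self) -> float:
        """Planted trapezoid area below baseline, in beats (decelerations)."""
        if self.amplitude_bpm >= 0:
            return 0.0
        return -self.amplitude_bpm * (self.duration_s - self.ramp_s) / 60.0


@dataclass
class TracePlan:
    """Everything needed to render one synthetic trace."""

    trace_id: str
    cohort: str
    duration_min: int
    sampling_rate: float
    basal_bpm: float
    drift_bpm: float
    stv_ms: float
    minute_kinds: np.ndarray  # 0 neutral, 1 high-variation, 2 low-variation
    events: list[PlannedEvent]
    missing_minutes: list[int]
    missing_extra: tuple[int, int] | None = None  # (start sample, n samples)


@dataclass
class PlantedTruth:
    """Ground truth planted in a synthetic trace."""

    events: list[PlannedEvent]
    baseline_bpm: np.ndarray
    high_intervals: list[tuple[float, float]]
    low_intervals: list[tuple[float, float]]
    missing_intervals: list[tuple[float, float]]
    features: dict[str, float]

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.amplitude_bpm == 0:
                raise ValidationError("planted event amplitude must be signed")
            if (ev.kind == "acceleration") != (ev.amplitude_bpm > 0):
                raise ValidationError("planted amplitude sign inconsistent with kind")


def _minute_intervals(kinds: np.ndarray, code: int) -> list[tuple[float, float]]:
    out = []
    m = 0
    while m < len(kinds):
        if kinds[m] == code:
            start = m
            while m < len(kinds) and kinds[m] == code:
                m += 1
            out.append((start * 60.0, m * 60.0))
        else:
            m += 1
    return out


def _plan_episodes(
    rng: np.random.Generator,
    analysed_min: int,
    total_min: int,
    high_min: int,
    low_min: int,
) -> np.ndarray:
    """Lay out high/low variation blocks inside the analysed window."""
    kinds = np.zeros(total_min, dtype=int)
    blocks = []
    if high_min > 0:
        blocks.append((1, high_min))
    if low_min > 0:
        blocks.append((2, low_min))
    rng.shuffle(blocks)
    # partition the remaining neutral minutes around the blocks (>=1 between)
    n_gaps = len(blocks) + 1
    neutral = analysed_min - sum(b[1] for b in blocks)
    inner = len(blocks) - 1 if len(blocks) > 1 else 0
    free = neutral - inner
    cuts = np.sort(rng.integers(0, free + 1, size=n_gaps - 1))
    gaps = np.diff(np.concatenate(([0], cuts, [free])))
    pos = 0
    for i, (code, length) in enumerate(blocks):
        pos += int(gaps[i]) + (1 if i > 0 else 0)
        kinds[pos : pos + length] = code
        pos += length
    return kinds


def plan_trace(
    config: SimulationConfig, cohort: str, rng: np.random.Generator, trace_id: str = "t0"
) -> TracePlan:
    """Draw per-trace feature targets and lay out a realisable plan."""
    config.validate()
    if cohort not in COHORTS:
        raise ConfigError(f"unknown cohort {cohort!r}")
    targets = config.cohort_feature_targets[cohort]
    dlo, dhi = config.duration_minutes_range
    duration = int(rng.integers(dlo, dhi + 1))
    analysed = min(duration, 60)

    basal = _sample_target(rng, targets["basal_fhr"])
    basal = float(np.clip(basal, 101.0, 148.0))
    stv = _sample_target(rng, targets["stv"])
    stv = max(0.0, float(stv))

    # Episode minutes respect the 5-of-6 persistence rule: any planted block
    # is >= 5 minutes, otherwise zero.  High episodes additionally need the
    # variability walk to span the 32 ms threshold, which requires a
    # sufficiently large step (STV) relative to the band.
    def block(name: str, feasible: bool) -> int:
        # episode persistence quantises sub-threshold draws: anything below
        # half the 5-minute episode floor collapses to zero, the rest is
        # promoted to at least one minimal episode
        raw = _sample_target(rng, targets[name])
        if raw < 2.5 or not feasible:
            return 0
        if raw < 6.5:
            return 5
        return int(round(raw))

    high = block("high_variation_min", 4.5 <= stv <= 14.5)
    low = block("low_variation_min", 0 < stv <= 28.0)
    # keep enough neutral minutes for events and separation
    max_ep = max(0, analysed - 8)
    if high + low > max_ep:
        low = max(0, min(low, max_ep - high))
        if high + low > max_ep:
            high = max(0, max_ep - low)
        high, low = (high if high >= 5 else 0), (low if low >= 5 else 0)
    kinds = _plan_episodes(rng, analysed, duration, high, low)

    # events: counts from targets, geometry with safety margins
    n_accel = int(round(_sample_target(rng, targets["accelerations"])))
    n_accel = max(0, min(n_accel, int(0.7 * analysed)))
    n_decel = max(0, int(round(_sample_target(rng, targets["decelerations"]))))
    events: list[PlannedEvent] = []
    mlb = 0.0
    if n_decel > 0:
        mlb = _sample_target(rng, targets["most_lost_beats"])
        mlb = max(13.8, float(mlb))
    specs: list[tuple[str, float, float]] = []  # (kind, duration_s, amplitude)
    for i in range(n_decel):
        lb = mlb if i == 0 else float(rng.uniform(13.8, mlb))
        depth = float(rng.uniform(24.0, 34.0))
        # trapezoid area (depth x (duration - ramp)) equals the drawn target
        dur_s = float(np.clip(lb * 60.0 / depth + 2.0, 36.0, 110.0))
        depth = lb * 60.0 / (dur_s - 2.0)
        specs.append(("deceleration", dur_s, -depth))
    for _ in range(n_accel):
        amp = float(rng.uniform(10.0 + config.event_margin_bpm, 22.0))
        dur_s = float(rng.uniform(15.0 + config.event_margin_s + 2.0, 42.0))
        specs.append(("acceleration", dur_s, amp))

    # place events in neutral minutes, >= 1 minute clear of episode blocks
    placeable = np.flatnonzero(kinds[:analysed] == 0)
    buffered = set(placeable.tolist())
    for m in np.flatnonzero(kinds != 0):
        buffered.discard(m - 1)
        buffered.discard(m + 1)
    segments: list[tuple[float, float]] = []
    run: list[int] = []
    for m in sorted(buffered):
        if run and m != run[-1] + 1:
            segments.append((run[0] * 60.0 + 2.0, (run[-1] + 1) * 60.0 - 2.0))
            run = []
        run.append(m)
    if run:
        segments.append((run[0] * 60.0 + 2.0, (run[-1] + 1) * 60.0 - 2.0))
    gap = 8.0
    for kind, dur_s, amp in sorted(specs, key=lambda s: -s[1]):
        fits = [i for i, (a, b) in enumerate(segments) if b - a >= dur_s + gap]
        if not fits:
            continue  # no room; the planted truth reflects what was placed
        i = int(rng.choice(fits))
        a, b = segments[i]
        onset = float(rng.uniform(a, b - dur_s - gap))
        events.append(PlannedEvent(kind=kind, onset_s=onset, duration_s=dur_s,
                                   amplitude_bpm=amp))
        segments[i] = (onset + dur_s + gap, b)
        if onset - a >= 60.0:
            segments.append((a, onset - 4.0))
    events.sort(key=lambda e: e.onset_s)

    # whole-minute signal-loss blackouts in event-free neutral minutes
    flo, fhi = config.signal_loss_fraction_range
    frac = float(rng.uniform(flo, fhi))
    n_samples = int(round(duration * 60 * config.sampling_rate))
    per_min = int(round(60 * config.sampling_rate))
    target_missing = int(round(frac * n_samples))
    event_minutes = set()
    for ev in events:
        for m in range(int(ev.onset_s // 60), int((ev.offset_s + gap) // 60) + 1):
            event_minutes.add(m)
    candidates = [
        m for m in range(duration)
        if kinds[m] == 0 and m not in event_minutes
    ]
    rng.shuffle(candidates)
    missing_minutes = candidates[: target_missing // per_min]
    remainder = target_missing - len(missing_minutes) * per_min
    extra = None
    if remainder > 0:
        # the partial block goes beyond the analysed window if there is
        # room, so it can never disturb a planted episode; otherwise the
        # remainder is dropped and the planted truth records what was placed
        beyond = [m for m in range(60, duration) if m not in missing_minutes
                  and m not in event_minutes and kinds[m] == 0]
        if beyond:
            extra = (beyond[0] * per_min, remainder)

    drift = float(rng.uniform(*config.drift_bpm_range))
    return TracePlan(
        trace_id=trace_id,
        cohort=cohort,
        duration_min=duration,
        sampling_rate=config.sampling_rate,
        basal_bpm=basal,
        drift_bpm=drift,
        stv_ms=stv,
        minute_kinds=kinds,
        events=events,
        missing_minutes=sorted(missing_minutes),
        missing_extra=extra,
    )


# ---------------------------------------------------------------------------
# rendering


def _band_width(kind: int, stv: float) -> float:
    """Pulse-interval excursion band (ms) per variation regime.

    Bands are integer multiples of the walk step so the zigzag lands exactly
    on the walls; the per-minute range of epoch pulse intervals then equals
    the band width, pinning the minute's classification.
    """
    if stv <= 0:
        return 0.0
    if kind == 1:  # high variation: range comfortably above 32 ms
        m = max(2, min(8, int(44.0 // stv)))
        return m * stv
    if kind == 2:  # low variation: range comfortably below 30 ms
        return max(1, int(24.0 // stv)) * stv
    return 31.0  # neutral: pinned between the 30 and 32 ms thresholds


def _variability_walk(
    kinds_per_minute: np.ndarray, stv: float, n_epochs: int, rng: np.random.Generator
) -> np.ndarray:
    """Bounded zigzag on the pulse-interval scale with mean |step| = stv."""
    w = np.zeros(n_epochs)
    if stv <= 0:
        return w
    n_min = len(kinds_per_minute)
    epm = int(round(60.0 / EPOCH_S))

    def new_step(kind: int, band: float) -> float:
        if kind != 0:
            return stv
        # neutral band is not a multiple of the step; mix traversal lengths
        ratio = band / stv
        m_lo = max(1, int(ratio))
        m = m_lo + (1 if rng.random() < ratio - m_lo else 0)
        return band / m

    v, direction = 0.0, 1.0
    prev_kind = -1
    step = stv
    for e in range(n_epochs):
        kind = int(kinds_per_minute[min(e // epm, n_min - 1)])
        band = _band_width(kind, stv)
        half = band / 2.0
        if kind != prev_kind:
            v = float(np.clip(v, -half, half))
            step = new_step(kind, band)
            prev_kind = kind
        nxt = v + direction * step
        if nxt >= half - 1e-9:
            nxt = half
            direction = -1.0
            step = new_step(kind, band)
        elif nxt <= -half + 1e-9:
            nxt = -half
            direction = 1.0
            step = new_step(kind, band)
        w[e] = nxt
        v = nxt
    return w


def _event_profile(plan: TracePlan, time_s: np.ndarray) -> np.ndarray:
    prof = np.zeros(len(time_s))
    for ev in plan.events:
        r = ev.ramp_s
        t = time_s
        rise = np.clip((t - ev.onset_s) / r, 0.0, 1.0)
        fall = np.clip((ev.offset_s - t) / r, 0.0, 1.0)
        shape = np.clip(np.minimum(rise, fall), 0.0, 1.0)
        inside = (t >= ev.onset_s) & (t < ev.offset_s)
        prof += np.where(inside, shape * ev.amplitude_bpm, 0.0)
    return prof


def render_trace(
    plan: TracePlan, config: SimulationConfig, rng: np.random.Generator
) -> tuple[FHRTrace, PlantedTruth]:
    """Render a plan into samples plus its planted truth."""
    fs = plan.sampling_rate
    n = int(round(plan.duration_min * 60 * fs))
    time_s = np.arange(n) / fs
    total_s = plan.duration_min * 60.0
    baseline = plan.basal_bpm + plan.drift_bpm * (time_s / total_s - 0.5)

    n_epochs = int(math.ceil(n / (EPOCH_S * fs)))
    w = _variability_walk(plan.minute_kinds, plan.stv_ms, n_epochs, rng)
    if config.epoch_jitter_ms > 0:
        w = w + rng.normal(0.0, config.epoch_jitter_ms, size=n_epochs)
    epoch_of = np.minimum((time_s / EPOCH_S).astype(int), n_epochs - 1)
    # variability is damped inside planted events so the planted amplitude
    # (not the wiggle) governs whether detection criteria are met
    damp = np.ones(n)
    for ev in plan.events:
        damp[(time_s >= ev.onset_s) & (time_s < ev.offset_s)] = 0.3
    pulse = 60000.0 / baseline + damp * w[epoch_of]
    if config.sample_noise_ms > 0:
        pulse = pulse + rng.normal(0.0, config.sample_noise_ms, size=n)
    fhr = 60000.0 / pulse + _event_profile(plan, time_s)

    mask = np.zeros(n, dtype=bool)
    per_min = int(round(60 * fs))
    for m in plan.missing_minutes:
        mask[m * per_min : (m + 1) * per_min] = True
    if plan.missing_extra is not None:
        start, count = plan.missing_extra
        mask[start : start + count] = True
    fhr = np.where(mask, np.nan, fhr)

    trace = FHRTrace(
        trace_id=plan.trace_id,
        time_s=time_s,
        fhr_bpm=fhr,
        missing_mask=mask,
        sampling_rate=fs,
        cohort=plan.cohort,
    )
    analysed_kinds = plan.minute_kinds[: min(plan.duration_min, 60)]
    decel_losses = [ev.lost_beats for ev in plan.events if ev.kind == "deceleration"]
    missing_iv = [(m * 60.0, (m + 1) * 60.0) for m in plan.missing_minutes]
    if plan.missing_extra is not None:
        start, count = plan.missing_extra
        missing_iv.append((start / fs, (start + count) / fs))
    truth = PlantedTruth(
        events=list(plan.events),
        baseline_bpm=baseline,
        high_intervals=_minute_intervals(plan.minute_kinds, 1),
        low_intervals=_minute_intervals(plan.minute_kinds, 2),
        missing_intervals=missing_iv,
        features={
            "basal_fhr": plan.basal_bpm,
            "accelerations": sum(e.kind == "acceleration" for e in plan.events),
            "decelerations": sum(e.kind == "deceleration" for e in plan.events),
            "most_lost_beats": max(decel_losses) if decel_losses else 0.0,
            "stv": plan.stv_ms,
            "high_variation_min": float((analysed_kinds == 1).sum()),
            "low_variation_min": float((analysed_kinds == 2).sum()),
            "signal_loss_fraction": float(mask.mean()),
        },
    )
    return trace, truth


def simulate_trace(
    config: SimulationConfig, cohort: str, seed: int
) -> tuple[FHRTrace, PlantedTruth]:
    """Simulate one trace; identical (config, cohort, seed) gives identical
    samples."""
    rng = np.random.default_rng(seed)
    plan = plan_trace(config, cohort, rng, trace_id=f"{cohort}-{seed}")
    return render_trace(plan, config, rng)


# ---------------------------------------------------------------------------
# cohorts


def _assign_subtypes(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> list[dict[str, bool]]:
    """Correlated subtype flags via a Gaussian copula; every record gets >=1.

    Adverse outcomes frequently co-occur, so flags share a latent severity
    factor with loading sqrt(subtype_correlation).
    """
    names = [s for s in SUBTYPES if config.subtype_prevalences.get(s, 0) > 0]
    if not names:
        raise ConfigError("at least one subtype prevalence must be positive")
    rho = float(np.clip(config.subtype_correlation, 0.0, 0.99))
    thresh = norm.ppf([config.subtype_prevalences[s] for s in names])
    shared = rng.normal(size=(n, 1))
    z = math.sqrt(rho) * shared + math.sqrt(1 - rho) * rng.normal(size=(n, len(names)))
    flags = z < thresh[None, :]
    none = ~flags.any(axis=1)
    if none.any():
        closest = np.argmax(thresh[None, :] - z[none], axis=1)
        flags[np.flatnonzero(none), closest] = True
    return [dict(zip(names, row.tolist())) for row in flags]


def simulate_records(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[CohortRecord]:
    """Draw cohort records (covariates, outcome, subtypes) without traces.

    Fetal sex is assigned by exact quota (round(male_fraction * n) per
    cohort) so cohort composition is deterministic; the assignment order is
    shuffled.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records: list[CohortRecord] = []
    glo, ghi = config.gestation_range
    dlo, dhi = config.duration_minutes_range
    blo, bhi = config.days_before_delivery_range
    for cohort, count in (("NPO", config.n_npo), ("APO", config.n_apo)):
        sexes = np.array(["female"] * count, dtype=object)
        n_male = int(round(config.male_fraction * count))
        sexes[:n_male] = "male"
        rng.shuffle(sexes)
        subtype_rows = (
            _assign_subtypes(config, count, rng) if cohort == "APO" else [{}] * count
        )
        for i in range(count):
            records.append(
                CohortRecord(
                    trace_id=f"{cohort}-{i:05d}",
                    pregnancy_id=f"P-{cohort}-{i:05d}",
                    cohort=cohort,
                    gestational_age_days=int(rng.integers(glo, ghi + 1)),
                    fetal_sex=str(sexes[i]),
                    duration_min=float(rng.integers(dlo, dhi + 1)),
                    days_before_delivery=(
                        float(rng.integers(blo, bhi + 1)) if cohort == "APO" else None
                    ),
                    subtypes=subtype_rows[i],
                )
            )
    return records


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[FHRTrace], list[CohortRecord], list[PlantedTruth]]:
    """Simulate both cohorts: traces, records and planted truths.

    Deterministic in ``config.seed``: per-trace generators are spawned from a
    single seed sequence.
    """
    config.validate()
    root = np.random.default_rng(config.seed)
    records = simulate_records(config, root)
    traces: list[FHRTrace] = []
    truths: list[PlantedTruth] = []
    streams = np.random.SeedSequence(config.seed).spawn(len(records))
    for rec, ss in zip(records, streams):
        rng = np.random.default_rng(ss)
        cfg = replace(config, duration_minutes_range=(int(rec.duration_min),) * 2)
        plan = plan_trace(cfg, rec.cohort, rng, trace_id=rec.trace_id)
        trace, truth = render_trace(plan, config, rng)
        trace.pregnancy_id = rec.pregnancy_id
        trace.gestational_age_days = rec.gestational_age_days
        trace.fetal_sex = rec.fetal_sex
        trace.days_before_delivery = rec.days_before_delivery
        traces.append(trace)
        truths.append(truth)
    return traces, records, truths


def export_fixture(
    traces: list[FHRTrace], records: list[CohortRecord], path: str | Path
) -> None:
    """Write trace CSVs plus a cohort table, round-trippable by trace_io."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for trace in traces:
        write_trace(trace, path / f"{trace.trace_id}.csv")
    write_cohort_table(records, path / "cohort.csv")


# ---------------------------------------------------------------------------
# cohort-level fidelity


def cohort_feature_medians(features: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-cohort medians of extracted features.

    ``most_lost_beats`` is summarised conditional on at least one detected
    deceleration (its unconditional median is 0 whenever the deceleration
    median is 0, which carries no information about deceleration severity).
    """
    out: dict[str, dict[str, float]] = {}
    for cohort, grp in features.groupby("cohort"):
        med = {f: float(grp[f].median()) for f in FEATURES}
        with_decel = grp[grp["decelerations"] > 0]
        med["most_lost_beats"] = (
            float(with_decel["most_lost_beats"].median()) if len(with_decel) else 0.0
        )
        out[str(cohort)] = med
    return out


def check_cohort_fidelity(
    features: pd.DataFrame,
    targets: dict[str, dict[str, FeatureTargets]] | None = None,
    tolerance: float = 0.15,
) -> dict:
    """Compare extracted cohort medians against configured targets.

    Returns per-feature relative errors, a pass flag at ``tolerance``, and the
    direction of the group difference.  Direction uses cohort means (for
    most-lost-beats, means conditional on >= 1 deceleration): several of the
    count-valued features have tied cohort medians whose group difference
    lives in the distribution tail.
    """
    targets = targets or DEFAULT_TARGETS
    medians = cohort_feature_medians(features)
    report: dict = {"features": {}, "passed": True}
    for fname in FEATURES:
        entry: dict = {}
        for cohort in COHORTS:
            target = targets[cohort][fname].median
            got = medians[cohort][fname]
            err = abs(got - target) / target if target > 0 else abs(got - target)
            ok = err <= tolerance
            entry[cohort] = {"target": target, "median": got, "error": err, "ok": ok}
            report["passed"] = report["passed"] and ok
        if fname == "most_lost_beats":
            sub = features[features["decelerations"] > 0]
            grp = sub.groupby("cohort")[fname].mean()
        else:
            grp = features.groupby("cohort")[fname].mean()
        diff = float(grp.get("APO", 0.0) - grp.get("NPO", 0.0))
        direction = "APO" if diff > 0 else ("NPO" if diff < 0 else "tie")
        expected = "APO" if fname in APO_HIGHER else "NPO"
        entry["direction"] = direction
        entry["direction_ok"] = direction == expected
        report["passed"] = report["passed"] and entry["direction_ok"]
        report["features"][fname] = entry
    return report
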