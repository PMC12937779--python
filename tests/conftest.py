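import numpy as np
import pytest

from ctgrisk.trace_io import FHRTrace

FS = 4.0


def make_trace(
    fhr,
    fs: float = FS,
    trace_id: str = "t",
    missing=None,
    t0: float = 0.0,
    **meta,
) -> FHRTrace:
    """Build a validated trace from a bpm array (NaN allowed with mask)."""
    fhr = np.asarray(fhr, dtype=float)
    n = len(fhr)
    if missing is None:
        missing = np.isnan(fhr)
    return FHRTrace(
        trace_id=trace_id,
        time_s=t0 + np.arange(n) / fs,
        fhr_bpm=fhr,
        missing_mask=np.asarray(missing, dtype=bool),
        sampling_rate=fs,
        **meta,
    )


def constant_trace(bpm: float = 140.0, minutes: float = 30.0, fs: float = FS, **kw):
    return make_trace(np.full(int(minutes * 60 * fs), float(bpm)), fs=fs, **kw)


def plateau_trace(
    base: float,
    delta: float,
    plateau_s: float,
    minutes: float = 20.0,
    start_s: float = 300.0,
    fs: float = FS,
):
    """Flat trace with one rectangular deviation of ``delta`` bpm."""
    fhr = np.full(int(minutes * 60 * fs), float(base))
    i0 = int(start_s * fs)
    i1 = i0 + int(plateau_s * fs)
    fhr[i0:i1] += delta
    return make_trace(fhr, fs=fs)


@pytest.fixture
def flat_trace():
    return constant_trace(140.0, 30.0)
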