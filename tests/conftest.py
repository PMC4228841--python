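import numpy as np
import pytest

from sppa3.signals import AlignedRecording, BeatSeries, SignalKind
from sppa3.synthcardio import SubjectParams, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_recording(rng):
    """A 3-axis BBI/SBP/RESP-like cloud with realistic scales."""
    n = 400
    pts = np.column_stack(
        [
            rng.normal(750, 40, n),
            rng.normal(120, 9, n),
            rng.normal(3.5, 0.4, n),
        ]
    )
    return AlignedRecording(
        signals=(SignalKind.BBI, SignalKind.SBP, SignalKind.RESP),
        points=pts,
        beat_times=np.arange(n, dtype=float),
    )


@pytest.fixture(scope="session")
def short_subject():
    """One deterministic synthetic subject (10-min recording)."""
    return generate_subject(SubjectParams(seed=42, duration_s=600.0))


def make_series(values, kind=SignalKind.BBI, times=None):
    values = np.asarray(values, float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    return BeatSeries(kind=kind, times=times, values=values)
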