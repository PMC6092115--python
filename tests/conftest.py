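import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pfk.core import UniformTimeSeries

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 200.0


def make_series(values, fs=FS, t0=0.0, **kw) -> UniformTimeSeries:
    return UniformTimeSeries(np.asarray(values, dtype=float), fs=fs, t0=t0, **kw)


@pytest.fixture
def sine_series():
    """Factory for sinusoid series: sine(freq, amp, duration, fs, t0, offset)."""

    def _make(freq, amp=1.0, duration=10.0, fs=FS, t0=0.0, offset=0.0):
        n = int(round(duration * fs)) + 1
        t = t0 + np.arange(n) / fs
        return UniformTimeSeries(offset + amp * np.sin(2 * np.pi * freq * t), fs=fs, t0=t0)

    return _make
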