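import numpy as np
import pytest

from puffs import load_reference_model
from puffs.topography import FlowTrace


@pytest.fixture(scope="session")
def reference_models():
    """The packaged TPM surface + nicotine line (device/e-liquid specific)."""
    return load_reference_model()


def make_rect_trace(pulses, fs=100.0, t_end=None):
    """Render rectangular pulses [(start, duration, height), ...] on a sampling grid.

    Pulse edges are aligned to the grid, so the trapezoidal integral of the
    rendered trace over a pulse equals height x duration exactly.
    """
    if t_end is None:
        t_end = max(s + d for s, d, _ in pulses) + 1.0
    dt = 1.0 / fs
    time = np.arange(0.0, t_end + dt / 2, dt)
    flow = np.zeros_like(time)
    for start, dur, height in pulses:
        i0 = int(round(start * fs))
        i1 = int(round((start + dur) * fs))
        flow[i0 : i1 + 1] = height
    return FlowTrace(time, flow)


@pytest.fixture
def rect_trace_factory():
    return make_rect_trace
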