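import numpy as np
import pytest

from adgif.model import simulate
from adgif.protocol import RecordingSet, default_ground_truth, ou_current


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def short_recording(ground_truth):
    """20-s noiseless dual-OU recording from the ground-truth model.

    One repetition, entirely training; used by the fitting tests for exact
    parameter recovery.
    """
    dt = 0.1
    duration = 20000.0
    i_s = ou_current(400.0, 300.0, 3.0, duration, dt, seed=11)
    i_d = ou_current(400.0, 300.0, 3.0, duration, dt, seed=12)
    trace = simulate(ground_truth, i_s, i_d, dt)
    return RecordingSet(dt, i_s, i_d, [trace.v_s], [trace.v_d],
                        [trace.spike_times], split_ms=duration,
                        ground_truth=ground_truth)
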