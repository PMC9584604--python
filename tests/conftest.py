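import numpy as np
import pytest

from fretkin import (
    PhotophysicsModel,
    build_scheme,
    default_model,
    simulate_traces,
)
from fretkin.idealize import IdealizedTrace


@pytest.fixture(scope="session")
def control_scheme():
    return build_scheme("control", include_dark_arrival=True)


@pytest.fixture(scope="session")
def photophysics_15ms():
    return PhotophysicsModel()


@pytest.fixture(scope="session")
def hmm4():
    return default_model()


@pytest.fixture(scope="session")
def control_traces(control_scheme, photophysics_15ms):
    """Shared control-condition trace set (200 traces, 10 s, seed 42)."""
    return [
        t
        for t in simulate_traces(
            control_scheme, photophysics_15ms, 200, 10.0, seed=42, condition="control"
        )
        if t.n_frames > 0
    ]


def ideal_from_states(states, frame_period=0.015, fret=None, model=None, trace_id=None):
    """Build an IdealizedTrace directly from a state sequence (test helper)."""
    states = np.asarray(states, dtype=np.intp)
    if model is None:
        model = default_model()
    if fret is None:
        fret = model.emission_means[states]
    return IdealizedTrace(
        state_seq=states,
        frame_period=frame_period,
        fret=np.asarray(fret, dtype=float),
        model=model,
        trace_id=trace_id,
    )
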