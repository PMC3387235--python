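import numpy as np
import pytest

from mitotrace.trace_io import Event, EventLog, Trace


@pytest.fixture
def clock():
    """5 Hz time base factory."""

    def make(t_end: float, hz: float = 5.0) -> np.ndarray:
        return np.round(np.arange(0.0, t_end + 0.5 / hz, 1.0 / hz), 6)

    return make


@pytest.fixture
def endpoint_trace(clock):
    """MgG-style trace with clean post-EDTA (100 afu) and post-MgCl2 (600 afu)
    plateaus, plus the matching event log."""
    t = clock(120.0)
    sig = np.full_like(t, 350.0)
    sig[t >= 30.0] = 100.0
    sig[t >= 70.0] = 600.0
    events = EventLog([Event(30.0, "EDTA", 5.0, "mM"), Event(70.0, "MgCl2", 25.0, "mM")])
    return Trace(t, sig, units="afu", channel="MgG"), events
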