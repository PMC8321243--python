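import numpy as np
import pytest

from funcyto import synthetic as syn
from funcyto.traces import Condition, TimestampSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_schedule():
    """30-frame protocol with one condition, basal frames on both sides."""
    return TimestampSchedule([Condition("glp1", 10, 20)], total_frames=30)


@pytest.fixture
def protocol():
    """Perifusion-style 8-agent protocol used across pipeline tests."""
    return syn.standard_schedule(n_conditions=8)


@pytest.fixture(scope="session")
def sim_recording():
    """One mid-size simulated recording shared by read-only pipeline tests."""
    schedule = syn.standard_schedule(n_conditions=8)
    cells = syn.make_population(60, schedule, seed=11, marker_label="agent_7")
    donor, acceptor, truth = syn.simulate_traces(
        cells, schedule, syn.default_drift(0.03), schedule.total_frames, seed=11
    )
    return schedule, cells, donor, acceptor, truth
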