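import pytest

import meaburst as mb


@pytest.fixture(scope="session")
def layout():
    return mb.build_4q_layout()


@pytest.fixture(scope="session")
def short_recording(layout):
    """Two minutes of default-parameter synthetic activity plus ground truth."""
    params = mb.SimulationParams(seed=11, duration=120.0)
    spikes, truth = mb.simulate_recording(params, layout)
    return params, spikes, truth
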