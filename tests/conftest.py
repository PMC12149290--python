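import numpy as np
import pytest

from oculonback import TaskConfig, default_neuron_panel, generate_session
from oculonback.simulate import Archetype


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def small_session(task_config):
    """A compact session with eye traces for behavior/io/cli tests."""
    specs = default_neuron_panel(
        2, archetypes=(Archetype.MEMORY, Archetype.VISUAL, Archetype.NULL)
    )
    return generate_session(
        task_config, 60, specs, seed=1234, stim_fraction=0.5, with_eye=True
    )


@pytest.fixture(scope="session")
def glm_session(task_config):
    """A spikes-only session sized for encoding-model tests."""
    specs = default_neuron_panel(
        4,
        archetypes=(
            Archetype.MEMORY,
            Archetype.EXTINCTION,
            Archetype.VISUAL,
            Archetype.NULL,
        ),
    )
    return generate_session(task_config, 350, specs, seed=77, with_eye=False)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
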