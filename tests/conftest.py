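import pytest

from gaitool.rubric import load_rubric
from gaitool.synthetic import SimulationConfig, generate, load_profiles


@pytest.fixture(scope="session")
def rubric():
    return load_rubric()


@pytest.fixture(scope="session")
def by_id(rubric):
    return {it.id: it for it in rubric}


@pytest.fixture(scope="session")
def profiles():
    return load_profiles()


@pytest.fixture(scope="session")
def normal_bout(profiles):
    """Noise-free normative bout, shared across tests (generation is pure)."""
    return generate(profiles["normal"], SimulationConfig(seed=7))
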