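import numpy as np
import pytest

from emglfm import GeneratorConfig, generate_study, make_model_template, simulate_study


@pytest.fixture(scope="session")
def tiny_config():
    """A raw-bundle-sized config: 1+1 subjects, 2 sessions, 5 marbles."""
    return GeneratorConfig(n_per_group=1, n_sessions=2, n_marbles=5, seed=7)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config, tmp_path_factory):
    """An on-disk raw-trace study bundle shared across tests."""
    path = tmp_path_factory.mktemp("bundle") / "study"
    generate_study(tiny_config, path)
    return path


@pytest.fixture(scope="session")
def templates(tiny_config):
    return make_model_template(tiny_config)


@pytest.fixture(scope="session")
def small_study():
    """In-memory envelope-fidelity study: 6+6 subjects, 6 sessions."""
    return simulate_study(GeneratorConfig(n_per_group=6, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
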