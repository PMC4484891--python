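import pytest

from racua.config import default_parameter_set
from racua.synthetic import make_synthetic_life_table


@pytest.fixture(scope="session")
def base_config():
    return default_parameter_set()


@pytest.fixture()
def config(base_config):
    """Fresh deep copy so tests may mutate freely."""
    return base_config.model_copy(deep=True)


@pytest.fixture(scope="session")
def life_table():
    return make_synthetic_life_table()
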