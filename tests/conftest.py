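import pytest

from tdm1cea import default_config, evaluate_strategy
from tdm1cea.synthetic import life_table_from_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def life_table(config):
    return life_table_from_config(config)


@pytest.fixture(scope="session")
def base_outcomes(config, life_table):
    """Both strategy arms evaluated once at the fixture configuration."""
    comp = evaluate_strategy("trastuzumab", config, life_table)
    intv = evaluate_strategy("tdm1", config, life_table)
    return comp, intv
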