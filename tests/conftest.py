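import pytest

from dosekit import DecayData, PipelineConfig
from dosekit.reference import intratumoral_summary, intratumoral_table


@pytest.fixture(scope="session")
def decay():
    return DecayData()


@pytest.fixture(scope="session")
def it_table():
    """Packaged intratumoral biodistribution fixture (4 pseudo-animals)."""
    return intratumoral_table()


@pytest.fixture(scope="session")
def it_summary():
    """Published intratumoral per-(organ, time) mean/SD summary."""
    return intratumoral_summary()


@pytest.fixture()
def local_np_config():
    """Pipeline config with the pure local-deposition S model."""
    return PipelineConfig(s_model="local_np_only")
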