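import pytest

from radkin import fixture_path
from radkin.config import RunConfig, load_config


def _load(name: str) -> RunConfig:
    return load_config(str(fixture_path(name)))


@pytest.fixture()
def table1_config() -> RunConfig:
    """Aqueous-medium channel inputs for both compounds (published table)."""
    return _load("table1_water")


@pytest.fixture()
def table2_config() -> RunConfig:
    """Lipid-medium (pentyl ethanoate) channel inputs for both compounds."""
    return _load("table2_pentyl_ethanoate")


@pytest.fixture()
def screen_config() -> RunConfig:
    """Reaction-Gibbs-energy screen entries (range endpoints)."""
    return _load("figure3_screen")
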