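import pytest

from orgredit.orgdata import load_table1, load_table2
from orgredit.synth_organelle import SimulationConfig, simulate_organelle


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def clean_truth():
    """Error-free 50-site truth set used by the round-trip suites."""
    config = SimulationConfig(seed=1, n_sites=50, sequencing_error_rate=0.0)
    return simulate_organelle(config)
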