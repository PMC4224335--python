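import numpy as np
import pytest

from mitonuclear import fixture_cohort, fixture_count_table, load_fixture, stratify


@pytest.fixture(scope="session")
def cohort():
    """The deterministic 1,477-record cohort expanded from the stratum counts."""
    return fixture_cohort()


@pytest.fixture(scope="session")
def count_table():
    return fixture_count_table()


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture
def rng():
    return np.random.default_rng(20140922 % 2**16)
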