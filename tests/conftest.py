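from decimal import Decimal

import pytest

import pollival as pv


@pytest.fixture(scope="session")
def tables():
    """The packaged state-level crop, microregion and municipality tables."""
    return pv.fixture_tables()


@pytest.fixture(scope="session")
def deps():
    return pv.fixture_dependence_table()


@pytest.fixture(scope="session")
def records():
    return pv.fixture_production_records()


@pytest.fixture(scope="session")
def valuated(records, deps):
    return pv.valuate(records, deps)


@pytest.fixture(scope="session")
def small_config():
    """A down-scaled generator config for fast multi-seed tests."""
    return pv.SyntheticConfig(n_municipalities=24, n_microregions=6)


@pytest.fixture()
def tiny_dataset():
    return pv.generate(pv.SyntheticConfig(n_municipalities=12, n_microregions=4), seed=7)


def D(x) -> Decimal:
    return Decimal(str(x))
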