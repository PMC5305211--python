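import pytest

from xlmap.fixtures import load_crosslink_table


@pytest.fixture(scope="session")
def crosslink_table():
    """The bundled published crosslink overview (16 rows, two experiments)."""
    return load_crosslink_table()


@pytest.fixture(scope="session")
def high_reliability(crosslink_table):
    """The five high-confidence H4-tail crosslinks used for docking."""
    return crosslink_table[crosslink_table.reliability == "high"]
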