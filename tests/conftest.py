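import numpy as np
import pytest

from dietbarcoder.simulate import (
    clupeid_analogue_reference,
    generate_reference_for_design,
    mock_from_table1,
)

MASTER_SEED = 1

CLUPEIDS = (
    "Clupea harengus",
    "Sprattus sprattus",
    "Sardina pilchardus",
    "Engraulis encrasicolus",
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture(scope="session")
def table1_design():
    return mock_from_table1()


@pytest.fixture(scope="session")
def table1_refdb(table1_design):
    return generate_reference_for_design(table1_design, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def clupeid_db_key():
    return clupeid_analogue_reference(seed=MASTER_SEED)


def random_seq(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
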