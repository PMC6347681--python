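import numpy as np
import pytest

from repevol.synthetic_data import (
    GermlineDB,
    RepertoireDesign,
    generate_germline_db,
    generate_repertoire,
)


@pytest.fixture(scope="session")
def germline_db() -> GermlineDB:
    return generate_germline_db(5, 3, seed=101)


@pytest.fixture(scope="session")
def germline_ref(germline_db):
    return germline_db.reference("SVH01", "SJH01")


@pytest.fixture(scope="session")
def tiny_bundle():
    """One tiny synthetic repertoire shared across tests (fixed seed)."""
    return generate_repertoire(RepertoireDesign.tiny(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
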