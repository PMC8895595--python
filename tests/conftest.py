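import pytest

from depositcomp import get_scheme
from depositcomp.sequence_io import ProteinRecord


@pytest.fixture(scope="session")
def intact():
    return get_scheme("intact")


@pytest.fixture(scope="session")
def hcl():
    return get_scheme("hcl")


@pytest.fixture(scope="session")
def msa():
    return get_scheme("msa")


@pytest.fixture
def record():
    def _make(seq, id="p1"):
        return ProteinRecord(id=id, sequence=seq)

    return _make
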