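import pytest

from endodiv import io
from endodiv.community import build_abundance_matrix


@pytest.fixture(scope="session")
def records():
    """The packaged 28-isolate survey (leaf/root/flower)."""
    return io.load_isolates()


@pytest.fixture(scope="session")
def matrix(records):
    """Abundance matrix with shared labels merged across tissues."""
    return build_abundance_matrix(records, mode="label")


@pytest.fixture(scope="session")
def matrix_per_tissue(records):
    return build_abundance_matrix(records, mode="label_per_tissue")


@pytest.fixture(scope="session")
def gi_table():
    return io.load_gi()


@pytest.fixture(scope="session")
def ic50_table():
    return io.load_ic50()


@pytest.fixture(scope="session")
def zi_table():
    return io.load_zi()


@pytest.fixture(scope="session")
def mic_table():
    return io.load_mic()
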