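import pytest

from idrkit.sequence_io import ProteinRecord, load_fixtures


@pytest.fixture(scope="session")
def fixtures() -> dict[str, ProteinRecord]:
    return load_fixtures()


@pytest.fixture(scope="session")
def wt(fixtures) -> ProteinRecord:
    return fixtures["WT"]
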