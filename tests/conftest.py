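import pytest

import microspec as ms


@pytest.fixture(scope="session")
def constants_table():
    return ms.packaged_constants_table()


@pytest.fixture(scope="session")
def correction_records(constants_table):
    return ms.build_correction_records(constants_table)
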