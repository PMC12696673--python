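import pytest

import aafadapt as aaf


@pytest.fixture(scope="session")
def gradual():
    return aaf.make_schedule("gradual")


@pytest.fixture(scope="session")
def sudden():
    return aaf.make_schedule("sudden")


@pytest.fixture(scope="session")
def shift():
    return aaf.DEFAULT_SHIFT


@pytest.fixture(scope="session")
def paper():
    return aaf.load_paper_fixture()
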