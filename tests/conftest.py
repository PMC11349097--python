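import pytest

from neomer.scaffold import make_scaffold, load_aptamarkers


@pytest.fixture(scope="session")
def scaffold8():
    return make_scaffold(8)


@pytest.fixture(scope="session")
def scaffold4():
    return make_scaffold(4)


@pytest.fixture(scope="session")
def aptamarkers():
    return load_aptamarkers()
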