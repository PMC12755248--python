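import pytest

from rfwalk import default_labels, enumerate_trees


@pytest.fixture(scope="session")
def catalog4():
    return enumerate_trees(default_labels(4))


@pytest.fixture(scope="session")
def catalog5():
    return enumerate_trees(default_labels(5))


@pytest.fixture(scope="session")
def catalog6():
    return enumerate_trees(default_labels(6))
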