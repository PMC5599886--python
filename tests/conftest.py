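import pytest

from trackprov import load_registry

REAL_BUILDS = ("hg18", "hg19", "hg38", "mm9", "mm10", "dm3", "dm6")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def hg19(registry):
    return registry.lookup("hg19")


@pytest.fixture(scope="session")
def hg38(registry):
    return registry.lookup("hg38")


@pytest.fixture(scope="session")
def toy_a(registry):
    return registry.lookup("toyA")


@pytest.fixture(scope="session")
def toy_b(registry):
    return registry.lookup("toyB")
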