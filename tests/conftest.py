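import pytest

from capri.strategies import build_capri, enumerate_memory_one


@pytest.fixture(scope="session")
def capri2():
    return build_capri(2)


@pytest.fixture(scope="session")
def capri3():
    return build_capri(3)


@pytest.fixture(scope="session")
def memory_one_n2():
    return enumerate_memory_one(2)
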