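import pytest

from wormlead import compounds as cmp


@pytest.fixture(scope="session")
def library():
    return cmp.fixture_library()


@pytest.fixture(scope="session")
def by_id(library):
    return {c.id: c for c in library}


@pytest.fixture(scope="session")
def descriptors(library):
    return {c.id: cmp.compute_descriptors(c) for c in library}
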