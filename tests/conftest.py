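import pytest

from elasticdms.config import DEFAULT_PARAMS, default_constructs
from elasticdms.synthetic import LibrarySpec, build_library


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def constructs():
    return {c.name: c for c in default_constructs()}


@pytest.fixture(scope="session")
def library_spec():
    return LibrarySpec()


@pytest.fixture(scope="session")
def library(library_spec):
    return build_library(library_spec)
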