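import pytest

from flavomics.library import default_library


@pytest.fixture(scope="session")
def lib():
    return default_library()
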