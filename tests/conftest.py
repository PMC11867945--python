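import pytest

from crcscreen import default_parameters


@pytest.fixture(scope="session")
def params():
    """Packaged defaults with the bundled synthetic life table."""
    return default_parameters()


@pytest.fixture(scope="session")
def params_flat():
    """Packaged defaults with flat background mortality (no life table)."""
    return default_parameters(life_table=False)
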