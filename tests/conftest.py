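import pytest

from idti import ActivationParams, ChannelBiophysics, corticospinal_bundle


@pytest.fixture(scope="session")
def cst_bundle():
    """The built-in corticospinal-tract bundle (five diameter classes)."""
    return corticospinal_bundle()


@pytest.fixture(scope="session")
def chans():
    return ChannelBiophysics()


@pytest.fixture(scope="session")
def params():
    return ActivationParams()
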