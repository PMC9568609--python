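import pytest
from hypothesis import settings

import dematel_taism as dt

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def nssi():
    """The bundled 13-factor adolescent NSSI system and its matrix O."""
    return dt.nssi_fixture()


@pytest.fixture(scope="session")
def nssi_report(nssi):
    """Full pipeline run on the bundled NSSI system."""
    system, O = nssi
    return dt.analyse(system, O)
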