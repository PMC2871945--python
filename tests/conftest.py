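import pytest
from hypothesis import settings

from lepirisk import species_profile

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def butterfly():
    """Shared I. io / V. atalanta profile (nettle host, LC50 5800)."""
    return species_profile("inachis_io")


@pytest.fixture(scope="session")
def moth():
    """P. xylostella profile (Brassicaceae host, LC50 3626)."""
    return species_profile("plutella_xylostella")
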