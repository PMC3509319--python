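import pytest

from slacq.synth import FamilyConfig, make_benchmark


@pytest.fixture(scope="session")
def slac_bundle():
    """One SLAC-like benchmark family at the default study conditions."""
    return make_benchmark(FamilyConfig(seed=11))


@pytest.fixture(scope="session")
def almt_bundle():
    """One ALMT/QUAC-like benchmark family (6+2 TM architecture)."""
    return make_benchmark(FamilyConfig(family="almt", seed=11))
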