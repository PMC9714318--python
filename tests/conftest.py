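import pytest

from mistsim import RateSet, VesselParams


@pytest.fixture(scope="session")
def std_params() -> VesselParams:
    """The standard condition set: q=0.9, m=0.2, ratio 5, p=1e-6, 10% stems."""
    return VesselParams()


@pytest.fixture(scope="session")
def std_rates(std_params) -> RateSet:
    return RateSet.from_params(std_params)
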