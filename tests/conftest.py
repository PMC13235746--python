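import numpy as np
import pytest

from nitrocrm import CommunityState, SupplySpec, builtin_trait_fixture


@pytest.fixture(scope="session")
def traits():
    return builtin_trait_fixture()


@pytest.fixture()
def supply_b1():
    """OM-limited single-B1 reference supply: 1 μM OM-N, 30 μM NO3-N."""
    return SupplySpec.om_no3(1.0, 30.0)


@pytest.fixture()
def all_present():
    def _make(supply: SupplySpec, density: float = 1e-3) -> CommunityState:
        return CommunityState(np.full(7, density), supply.s.copy())

    return _make
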