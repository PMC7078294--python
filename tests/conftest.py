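import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pbentropy.synthetic_ensembles import EnsembleSpec, RegionSpec, build_ensemble

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


THREE_REGION_LAYOUT = (
    RegionSpec(0, 10, ("m",)),
    RegionSpec(10, 20, ("m", "d")),
    RegionSpec(20, 30, ("a", "c", "d", "e", "g", "m", "n", "o")),
)


def region_interior(region: RegionSpec) -> range:
    """Positions whose full assignment window lies inside the region."""
    return range(region.start + 2, region.end - 2)


@pytest.fixture(scope="session")
def three_region_spec() -> EnsembleSpec:
    """Rigid / flexible / disordered chain, small enough for unit tests."""
    return EnsembleSpec(chain_length=30, n_models=50, regions=THREE_REGION_LAYOUT, seed=42)


@pytest.fixture(scope="session")
def three_region_ensemble(three_region_spec):
    return build_ensemble(three_region_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
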