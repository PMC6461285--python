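import numpy as np
import pytest

from emsloc import CoverageInstance, RegionParams, generate_region
from emsloc.scenarios import prepare_inputs


def make_random_instance(rng: np.random.Generator) -> CoverageInstance:
    """Small random instance inside the enumeration oracle's guard."""
    n_demand = int(rng.integers(4, 13))
    n_bases = int(rng.integers(2, 7))
    cover = rng.random((n_demand, n_bases)) < 0.4
    weights = rng.integers(0, 10, size=n_demand).astype(float)
    if weights.sum() == 0:
        weights[0] = 1.0
    q = float(rng.choice([0.0, 0.15, 0.35, 0.5]))
    p = int(rng.integers(1, 5))
    max_bases = None if rng.random() < 0.5 else int(rng.integers(1, n_bases + 1))
    return CoverageInstance(weights=weights, cover=cover, q=q, p=p,
                            max_bases=max_bases)


@pytest.fixture(scope="session")
def small_region():
    """Default three-town synthetic region used across integration tests."""
    return generate_region(RegionParams(seed=3))


@pytest.fixture(scope="session")
def small_region_inputs(small_region):
    """(weights, cover, current_idx, labels, eligible) for the small region."""
    return prepare_inputs(small_region.demand, small_region.bases,
                          small_region.network)
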