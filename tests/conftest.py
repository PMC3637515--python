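import numpy as np
import pytest

import phyrn


@pytest.fixture(scope="session")
def small_family() -> phyrn.SimulatedFamily:
    """A 6-leaf family at moderate conservation, small enough for fast tests."""
    return phyrn.simulate_family(
        phyrn.SimulationConfig(
            n_leaves=6, root_length=80, flank_length=20, rng_seed=5
        )
    )


@pytest.fixture(scope="session")
def small_library(small_family) -> phyrn.PSSMLibrary:
    seeds = phyrn.extract_domains(
        small_family.leaf_records, small_family.domain_boundaries
    )
    return phyrn.build_library(
        seeds, small_family.leaf_records, iterations=1, n_decoys=60, rng_seed=0
    )


@pytest.fixture(scope="session")
def small_matrix(small_family, small_library) -> phyrn.CompositeMatrix:
    return phyrn.build_composite_matrix(
        small_family.leaf_records, small_library, b_fraction=1.0
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
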