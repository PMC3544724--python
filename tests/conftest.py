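import numpy as np
import pytest

from telandscape.sim import (
    build_te_library,
    default_regime,
    sample_ests,
    simulate_genome,
)


@pytest.fixture(scope="session")
def small_library():
    return build_te_library(10, seed=11)


@pytest.fixture(scope="session")
def small_genome(small_library):
    """Three 150-kb scaffolds, one per density regime, with truth."""
    regimes = [
        default_regime("te_rich", 150_000),
        default_regime("balanced", 150_000),
        default_regime("gene_rich", 150_000),
    ]
    assembly, truth = simulate_genome(regimes, te_library=small_library, seed=29)
    return assembly, truth


@pytest.fixture(scope="session")
def small_genome_with_ests(small_genome, small_library):
    assembly, truth = small_genome
    ests = sample_ests(
        truth,
        assembly,
        small_library,
        expressed_fraction=0.4,
        n_ests=80,
        length_range=(150, 400),
        seed=37,
    )
    return assembly, truth, ests


@pytest.fixture
def rng():
    return np.random.default_rng(123)
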