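import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from scalescape import (
    CodonUsage,
    NucleobaseTarget,
    ProfileCache,
    SyntheticSpec,
    generate_proteome,
)


@pytest.fixture(scope="session")
def uniform_usage():
    return CodonUsage.uniform()


@pytest.fixture(scope="session")
def small_proteome():
    """30 pairs of fixed length 100, uniform usage — fast shared substrate."""
    return generate_proteome(
        SyntheticSpec(n_pairs=30, length_distribution=("fixed", 100), seed=11)
    )


@pytest.fixture(scope="session")
def small_cache(small_proteome):
    return ProfileCache(small_proteome)


@pytest.fixture(scope="session")
def varied_proteome():
    """Pairs with varied lengths, for length-sensitive properties."""
    return generate_proteome(
        SyntheticSpec(n_pairs=25, length_distribution=("uniform", 22, 120), seed=7)
    )
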