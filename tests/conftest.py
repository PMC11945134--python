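import numpy as np
import pytest

from mabckit.genmap import Chromosome, GeneticMap
from mabckit.synthetic_data import make_maize_like_map


@pytest.fixture(scope="session")
def default_map() -> GeneticMap:
    return make_maize_like_map()


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    """Three short chromosomes with physical lengths, cheap to simulate."""
    return GeneticMap(
        [
            Chromosome("chr1", 100.0, length_bp=20_000),
            Chromosome("chr2", 80.0, length_bp=16_000),
            Chromosome("chr8", 60.0, length_bp=12_000),
        ]
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
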