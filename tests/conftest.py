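import numpy as np
import pytest

from fluorocode.genome import ENZYMES, find_sites, synthetic_genome_with_sites


@pytest.fixture(scope="session")
def t7like_genome():
    """Synthetic stand-in for the T7 genome: 39,937 bp, exactly 111 M.TaqI sites."""
    return synthetic_genome_with_sites(
        39_937, ENZYMES["M.TaqI"], 111, seed=11, genome_id="t7like"
    )


@pytest.fixture(scope="session")
def taqi_map(t7like_genome):
    return find_sites(t7like_genome, ENZYMES["M.TaqI"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
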