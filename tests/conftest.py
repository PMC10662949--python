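import numpy as np
import pytest

from telodisjoin import genome as genome_mod
from telodisjoin import pipeline


@pytest.fixture(scope="session")
def toy_genomes():
    """Default (target, spikein) pair: 3 x 300 kb chromosomes."""
    return genome_mod.build_toy_genome()


@pytest.fixture(scope="session")
def target_genome(toy_genomes):
    return toy_genomes[0]


@pytest.fixture(scope="session")
def spikein_genome(toy_genomes):
    return toy_genomes[1]


@pytest.fixture(scope="session")
def hic_genome():
    """Unequal chromosome lengths suited to 150-kb end regions at 5 kb."""
    target, _ = genome_mod.build_toy_genome(pipeline.hic_genome_config())
    return target


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
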