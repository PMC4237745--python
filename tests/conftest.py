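import numpy as np
import pytest

from biomemory import genome as genome_mod
from biomemory import learning
from biomemory.thermo import DuplexConditions


@pytest.fixture(scope="session")
def learning_conditions():
    """The wet-protocol reaction condition: 1.6 uM oligo, 10/10/4 mM salts."""
    return DuplexConditions()


@pytest.fixture(scope="session")
def small_genome():
    return genome_mod.generate_genome(20_000, 0.5, seed=11, id="gA")


@pytest.fixture(scope="session")
def small_pool(small_genome):
    return genome_mod.dnase_fragment(small_genome, 200.0, seed=12)


@pytest.fixture(scope="session")
def small_tags():
    return learning.make_tag_library(300, seed=13)


@pytest.fixture(scope="session")
def learned_small(small_pool, small_tags):
    """One canonical A→E→D learning run at 25 °C on the small inputs."""
    return learning.run_learning(
        small_pool, small_tags, "AED", temperature=25.0, seed=14
    )


def make_tags_from_probes(probes: list[str], tag_seq=learning.DEFAULT_TAG_SEQ):
    """Build a TagLibrary with hand-chosen probe sequences."""
    from biomemory.seqs import encode

    mat = np.stack([encode(p) for p in probes])
    return learning.TagLibrary(tag_seq, mat, "biotin", seed=0)
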