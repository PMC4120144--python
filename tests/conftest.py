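import numpy as np
import pytest

from ranmap import build_index_pair
from ranmap.io import Genome
from ranmap.simulate import random_genome


@pytest.fixture(scope="session")
def small_genome():
    rng = np.random.default_rng(42)
    return random_genome(2_000, rng, "small")


@pytest.fixture(scope="session")
def small_pair(small_genome):
    return build_index_pair(small_genome)


@pytest.fixture(scope="session")
def bench_genome():
    """100-kb i.i.d. genome used by the end-to-end tests."""
    rng = np.random.default_rng(11)
    return random_genome(100_000, rng, "bench")


@pytest.fixture(scope="session")
def bench_pair(bench_genome):
    return build_index_pair(bench_genome)


@pytest.fixture()
def tiny_genome():
    return Genome(name="tiny", sequence="AACCGGTTAACCGGTT")
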