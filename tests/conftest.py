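import numpy as np
import pytest

from teharvest import fixtures as fx
from teharvest.search import Hit


@pytest.fixture(scope="session")
def ancestor():
    return fx.make_ancestor(aa_length=300, tir_length=26, seed=3)


@pytest.fixture(scope="session")
def small_fixture():
    """A 300 kb genome with 6 full + 6 fragmented copies at 2% divergence."""
    spec = fx.FixtureSpec(
        genome_length=300_000, n_full=6, n_fragment=6,
        sub_rate=0.02, indel_rate=0.002, seed=7,
    )
    return fx.plant_copies(spec)


@pytest.fixture(scope="session")
def small_library(small_fixture):
    return fx.library_for_ancestor(small_fixture.ancestor)


def make_hit(contig="c1", start=0, end=10, query="q1", strand="+", hid=None):
    return Hit(
        id=hid or f"{query}:{contig}:{start}-{end}:{strand}",
        query_id=query, contig=contig, start=start, end=end,
        strand=strand, frame=0, score=100, bitscore=50.0, evalue=1e-30,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
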