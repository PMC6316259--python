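import numpy as np
import pytest

from nbskit import simulate as sim
from nbskit.model import GeneModel


@pytest.fixture(scope="session")
def sim_genome():
    """One shared synthetic genome with planted clusters, family tiers and a
    segmental block (seed fixed for the whole session)."""
    return sim.simulate_genome(sim.default_recipe(11))


@pytest.fixture(scope="session")
def sim_recipe():
    return sim.default_recipe(11)


def make_gene(gene_id, start, end, chromosome="chr1", strand="+", **kw):
    return GeneModel(gene_id=gene_id, chromosome=chromosome, start=start,
                     end=end, strand=strand, **kw)


@pytest.fixture
def gene_factory():
    return make_gene


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
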