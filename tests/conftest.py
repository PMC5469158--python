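import numpy as np
import pytest

from mtsubst import (
    Alignment,
    RateHeterogeneity,
    SimulationSpec,
    SubstitutionModel,
    load_model,
    parse_newick,
    random_tree,
    simulate_alignment,
    uniform_model,
)


@pytest.fixture(scope="session")
def wag():
    return load_model("WAG")


@pytest.fixture(scope="session")
def lg():
    return load_model("LG")


@pytest.fixture(scope="session")
def mtzoa():
    return load_model("mtZoa")


@pytest.fixture(scope="session")
def uniform():
    return uniform_model()


@pytest.fixture(scope="session")
def random_model():
    """A seeded, irregular but valid substitution model."""
    rng = np.random.default_rng(42)
    r = np.zeros((20, 20))
    tril = np.tril_indices(20, k=-1)
    r[tril] = rng.lognormal(mean=0.0, sigma=1.0, size=190)
    r = r + r.T
    pi = rng.dirichlet(np.full(20, 5.0))
    return SubstitutionModel(name="random42", exchangeabilities=r, frequencies=pi)


@pytest.fixture
def fig_trees():
    """The worked five-taxon example: two inferred trees and the truth."""
    t = parse_newick("((1,2),4,(3,5));")
    t_prime = parse_newick("((1,5),2,(3,4));")
    truth = parse_newick("((1,2),5,(3,4));")
    return t, t_prime, truth


@pytest.fixture(scope="session")
def small_alignment(wag):
    """Six taxa, 200 sites, simulated under WAG with mild rate variation."""
    rng = np.random.default_rng(7)
    tree = random_tree(6, rng, branch_mean=0.2)
    het = RateHeterogeneity(alpha=1.0, v=0.1, C=4)
    aln = simulate_alignment(
        SimulationSpec(tree=tree, model=wag, het=het, n_sites=200, seed=11)
    )
    return tree, het, aln
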