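import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cetevol as cv

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_tree():
    return cv.demo_tree()


@pytest.fixture(scope="session")
def whale_tree(demo_tree):
    """8-cetacean subtree of the demo phylogeny."""
    mrca = demo_tree.mrca(list(cv.simulate.CETACEANS))
    return demo_tree.subtree(mrca.name)


@pytest.fixture(scope="session")
def sim300(demo_tree):
    """A 300-codon purifying (omega=0.2) simulation on the demo tree."""
    spec = cv.SimulationSpec(tree=demo_tree, length=300, seed=11, omega=0.2)
    aln, internal, site_class = cv.simulate_codon_alignment(spec)
    return aln, internal, site_class


@pytest.fixture(scope="session")
def fit_m0(sim300, demo_tree):
    aln, _, _ = sim300
    return cv.fit_model(aln, demo_tree, "one-ratio", seed=1)


@pytest.fixture(scope="session")
def fit_m1(sim300, demo_tree):
    aln, _, _ = sim300
    return cv.fit_model(aln, demo_tree, "M1", seed=1)


@pytest.fixture(scope="session")
def fit_m2(sim300, demo_tree):
    aln, _, _ = sim300
    return cv.fit_model(aln, demo_tree, "M2", seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_pi(rng: np.random.Generator) -> np.ndarray:
    pi = rng.dirichlet(np.full(61, 5.0))
    return pi / pi.sum()
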