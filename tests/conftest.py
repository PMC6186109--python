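import numpy as np
import pytest

from pqtree import Alignment, ScoreConfig, identity_matrix, blosum62


@pytest.fixture(scope="session")
def identity_cfg():
    return ScoreConfig(identity_matrix())


@pytest.fixture(scope="session")
def blosum_cfg():
    return ScoreConfig(blosum62())


@pytest.fixture
def toy_alignment():
    """Two identical-pair columns: the single quartet supports {s1,s2}|{s3,s4}."""
    return Alignment(("s1", "s2", "s3", "s4"), ("AA", "AA", "CC", "CC"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_case(n_leaves, length, subst, seed, alphabet="ACGT"):
    """A (true tree, alignment) pair evolved under the simple point model."""
    from pqtree import EvolveParams, evolve_alignment, random_topology

    gen = np.random.default_rng(seed)
    tree = random_topology(n_leaves, gen)
    aln = evolve_alignment(
        tree, EvolveParams(length=length, subst_prob=subst, alphabet=alphabet), gen
    )
    return tree, aln
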