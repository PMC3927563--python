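import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from promoterminer.seqio import NucleotideSequence, LabeledDataset
from promoterminer.synth import generate_feature_matrix


S20_RESIDUES = "CATAGCCATTGCATGACCCG"


@pytest.fixture
def s20():
    """The 20-nt worked-example sequence (5 A, 7 C, 4 G, 4 T)."""
    return NucleotideSequence("S20", S20_RESIDUES)


@pytest.fixture
def random_sequences():
    """200 random pure-ACGT sequences with lengths from 4 to 500."""
    rng = np.random.default_rng(42)
    seqs = []
    for i in range(200):
        n = int(rng.integers(4, 501))
        seqs.append(NucleotideSequence(
            f"r{i}", "".join(rng.choice(list("ACGT"), size=n))))
    return seqs


@pytest.fixture
def small_dataset(random_sequences):
    """50 random sequences with alternating labels."""
    seqs = random_sequences[:50]
    return LabeledDataset(seqs, [i % 2 for i in range(50)])


@pytest.fixture
def separable_matrix():
    """Strongly separated two-class Gaussian clouds (n=60, 8 features)."""
    X, y, truth = generate_feature_matrix(
        n=60, m=8, n_informative=8, effect=4.0, seed=11)
    return X, y


@pytest.fixture
def planted_matrix():
    """10 informative of 50 features, effect 2 sd, n=200."""
    X, y, truth = generate_feature_matrix(
        n=200, m=50, n_informative=10, effect=2.0, seed=5)
    return X, y, truth
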