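import numpy as np
import pytest

from bcmine import GeneratorSpec, ideal_helix, random_walk_fragment, synthetic_bank


@pytest.fixture
def helix12():
    return ideal_helix(12)


@pytest.fixture
def walk_bank(tmp_path):
    """10 random-walk decoys with a 9-residue helix planted in one of them."""
    specs = [GeneratorSpec("random_walk", length=30, seed=100 + i) for i in range(10)]
    bank, truth = synthetic_bank(specs, tmp_path / "bank",
                                 planted=(ideal_helix(9), 3, 12))
    return bank, truth


@pytest.fixture
def seeded_fragments():
    """A mixed population of fragments, lengths 4-30, deterministic."""
    frags = []
    for k in range(40):
        n = 4 + (k * 7) % 27
        frags.append(random_walk_fragment(n, seed=500 + k))
    return frags


def random_rotations(n, seed):
    from scipy.spatial.transform import Rotation

    return Rotation.random(n, rng=np.random.default_rng(seed)).as_matrix()
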