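import numpy as np
import pytest

from evoddg import SequenceProfile, read_structure
from evoddg.fixtures import FixtureSpec, make_structure
from evoddg.params import AA_INDEX, AMINO_ACIDS


def random_profile(rng: np.random.Generator, length: int) -> SequenceProfile:
    """A valid random profile: Dirichlet columns, random query consistent
    with positive query-residue frequency."""
    freqs = rng.dirichlet(np.full(20, 0.5), size=length)
    freqs = freqs + 1e-6  # keep every residue observable
    freqs /= freqs.sum(axis=1, keepdims=True)
    query = "".join(AMINO_ACIDS[rng.choice(20)] for _ in range(length))
    return SequenceProfile(query=query, freqs=freqs, depth=np.full(length, 10.0))


def onehot_profile(query: str) -> SequenceProfile:
    freqs = np.zeros((len(query), 20))
    for j, c in enumerate(query):
        freqs[j, AA_INDEX[c]] = 1.0
    return SequenceProfile(query=query, freqs=freqs, depth=np.ones(len(query)))


def structure_from_geometry(tmp_path, geometry, seed=0, name="toy.pdb"):
    path = tmp_path / name
    path.write_text(make_structure(FixtureSpec(seed=seed, structure_geometry=geometry)))
    return read_structure(path, "A")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
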