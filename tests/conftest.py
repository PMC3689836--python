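import numpy as np
import pytest

from bonylabyrinth import io


@pytest.fixture(scope="session")
def records():
    return io.load_packaged_measurements()


@pytest.fixture(scope="session")
def by_id(records):
    return {taxon.taxon_id: (taxon, rec) for taxon, rec in records}


@pytest.fixture(scope="session")
def specimens():
    return io.load_packaged_specimens()


@pytest.fixture()
def tree():
    # function-scoped: some tests reroot or otherwise mutate the tree
    return io.load_packaged_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(20130624)


def random_rotation(rng) -> np.ndarray:
    """A uniformly random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
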