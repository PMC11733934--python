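import numpy as np
import pytest

from hbdiff.complexes import FullAtomProtein
from hbdiff.fixtures import FixtureSpec, make_toy_complex


def random_rotation(rng) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def protein_from_atoms(atoms) -> FullAtomProtein:
    """atoms: list of (element, atom_name, res_type, res_index, chain, xyz)."""
    return FullAtomProtein(
        elements=[a[0] for a in atoms],
        atom_names=[a[1] for a in atoms],
        res_types=[a[2] for a in atoms],
        res_indices=np.array([a[3] for a in atoms]),
        chain_ids=[a[4] for a in atoms],
        positions=np.array([a[5] for a in atoms], dtype=float),
    )


@pytest.fixture(scope="session")
def toy_record():
    return make_toy_complex(FixtureSpec(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
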