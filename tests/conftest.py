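import numpy as np
import pytest

from abiface.structure_io import Structure


def atom_keys(structure: Structure) -> list[tuple]:
    return [(res.chain_id, res.seq_num, res.icode, a.name) for res, a in structure.atoms()]


def identity_pairing(structure: Structure) -> list[tuple[tuple, tuple]]:
    return [(k, k) for k in atom_keys(structure)]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation from a QR decomposition."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
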