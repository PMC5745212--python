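import numpy as np
import pytest

import hawkrank as hr


@pytest.fixture(scope="session")
def bundle() -> hr.ParameterBundle:
    return hr.ParameterBundle.default()


@pytest.fixture(scope="session")
def all20_peptide() -> hr.ProteinStructure:
    """One toy chain containing every standard residue once."""
    return hr.make_toy_protein(hr.ToySpec(20, "extended", seed=1, sequence=tuple(hr.ALL20)))


@pytest.fixture(scope="session")
def toy_complex() -> hr.ComplexPartition:
    return hr.make_toy_complex(n_rec=10, n_lig=6, gap=1.5, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_rigid(rng: np.random.Generator) -> hr.RigidTransform:
    """A uniformly random proper rotation plus a bounded translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return hr.RigidTransform(R, rng.uniform(-20, 20, size=3))
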