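import numpy as np
import pytest

from dtbind.config import ModelConfig
from dtbind.fixtures import make_toy_complex, make_toy_protein, stub_embedder
from dtbind.training import featurize_toy_complex


@pytest.fixture(scope="session")
def small_config() -> ModelConfig:
    """Narrow widths keep the unit tests fast; shapes stay general."""
    return ModelConfig(h1=32, h2=8, h3=32, h4=32, h5=32, h6=32, heads=4,
                       dropout=0.0)


@pytest.fixture(scope="session")
def default_config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def toy_protein():
    return make_toy_protein(20, seed=1)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(1)


@pytest.fixture(scope="session")
def featurized_complex(toy_complex, small_config):
    return featurize_toy_complex(toy_complex, small_config, with_hetero=True)


@pytest.fixture(scope="session")
def embedder():
    return stub_embedder()


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation and a bounded random translation."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31 - 1))).as_matrix()
    shift = rng.uniform(-20.0, 20.0, size=3)
    return rot, shift


def transform_protein(structure, rot, shift):
    """Apply a rigid motion to every atom of a ProteinStructure."""
    from dtbind.structure_io import AtomRecord, ProteinStructure, ResidueRecord
    residues = []
    for r in structure.residues:
        atoms = tuple(AtomRecord(a.name, a.element, rot @ a.xyz + shift)
                      for a in r.atoms)
        residues.append(ResidueRecord(r.chain_id, r.resnum, r.icode,
                                      r.resname, atoms))
    return ProteinStructure(residues=residues, name=structure.name)
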