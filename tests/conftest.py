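import numpy as np
import pytest

from ctxflex import SyntheticSpec, chain_profile, make_dataset

MINI_PDB = """\
ATOM      1  N   ALA A   1      -1.000   0.500   0.000  1.00  9.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00 20.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00 30.00           C
END
"""

MINI_PDB_HET = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 20.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00 30.00           C
HETATM    4  O   HOH A 101      10.000  10.000  10.000  1.00 50.00           O
HETATM    5  C1  LIG A 102      12.000  12.000  12.000  1.00 40.00           C
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


@pytest.fixture
def mini_pdb_het(tmp_path):
    path = tmp_path / "mini_het.pdb"
    path.write_text(MINI_PDB_HET)
    return path


@pytest.fixture(scope="session")
def planted_dataset():
    """20 compact synthetic proteins with catalytic sites planted at rigid residues."""
    spec = SyntheticSpec()
    chains, labels = make_dataset(20, spec, seed=7)
    return chains, labels


@pytest.fixture(scope="session")
def planted_profiles(planted_dataset):
    chains, _ = planted_dataset
    return [(c, chain_profile(c), None) for c in chains]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
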