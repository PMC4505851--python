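import numpy as np
import pytest

from loopstring.structures import select_representative_atoms
from loopstring.toyloop import build_toy_loop, generate_endpoint_conformations

DEFAULT_FLIPS = [(5, "psi", 180.0), (6, "psi", 180.0)]


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_loop(11, seed=3)


@pytest.fixture(scope="session")
def endpoint_pair(toy_model):
    return generate_endpoint_conformations(toy_model, DEFAULT_FLIPS)


@pytest.fixture(scope="session")
def rep_selection(endpoint_pair):
    return select_representative_atoms(endpoint_pair.state_a, 1, 11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.922  1.00  0.00           C
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA BSER A   1       2.000   0.000   0.000  0.40  0.00           C
ATOM      4  C   SER A   1       3.000   0.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture()
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture()
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p
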