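import numpy as np
import pytest

from loopgate.synth import make_gate_structure, make_spectra_and_traces


@pytest.fixture(scope="session")
def gate_closed():
    """Toy two-domain structure with both gate pairs at the closed 6.2 Å."""
    structure, manifest = make_gate_structure(gap=6.2, seed=0)
    return structure, manifest


@pytest.fixture(scope="session")
def gate_open():
    """Same scaffold with the CTD pair opened to 9.3 Å."""
    structure, manifest = make_gate_structure(gap=9.3, seed=0)
    return structure, manifest


@pytest.fixture(scope="session")
def spectro_data():
    """Noiseless spectra + turbidity trace with recorded ground truth."""
    return make_spectra_and_traces(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


MINIMAL_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   GLY A   1      12.759   7.078  -4.915  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.558   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.109   1.420   0.000  1.00  0.00           C
ENDMDL
END
"""

WATER_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   GLY A   1      12.759   7.078  -4.915  1.00  0.00           C
HETATM    4  O   HOH W 100       2.000   2.000   2.000  1.00  0.00           O
END
"""


@pytest.fixture()
def pdb_file(tmp_path):
    def _write(content, name="test.pdb"):
        path = tmp_path / name
        path.write_text(content)
        return path
    return _write
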