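import pytest

from siakit import Protein, load_panel


@pytest.fixture(scope="session")
def nuclease_panel():
    return load_panel(Protein.NUCLEASE_A)


@pytest.fixture(scope="session")
def lysozyme_panel():
    return load_panel(Protein.T4_LYSOZYME)


@pytest.fixture()
def single_oxygen_pdb(tmp_path):
    """A one-ATOM PDB file (one oxygen at the origin)."""
    path = tmp_path / "oxygen.pdb"
    path.write_text(
        "ATOM      1  O1  TOY A   1       0.000   0.000   0.000  1.00  0.00"
        "           O\nEND\n"
    )
    return path


@pytest.fixture()
def two_model_pdb(tmp_path):
    """An NMR-style file whose two MODEL blocks hold different coordinates."""
    path = tmp_path / "twomodel.pdb"
    path.write_text(
        "MODEL        1\n"
        "ATOM      1  C1  TOY A   1       0.000   0.000   0.000  1.00  0.00"
        "           C\n"
        "ENDMDL\n"
        "MODEL        2\n"
        "ATOM      1  C1  TOY A   1       5.000   0.000   0.000  1.00  0.00"
        "           C\n"
        "ENDMDL\n"
        "END\n"
    )
    return path
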