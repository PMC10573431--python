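import numpy as np
import pytest

from opreact import make_active_site
from opreact.datasets import (
    load_bche_adducts,
    load_bche_am1_table,
    load_bche_mm_table,
    load_cbdp_docking_poses,
)

THREE_ATOM_PDB = """\
ATOM      1  OG  SER A 198      10.000  10.000  10.000  1.00  0.00           O
HETATM    2  P   ADT A 900      11.000  10.500  10.200  1.00  0.00           P
HETATM    3  F   F   A 901      13.000  10.500  10.200  1.00  0.00           F
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


@pytest.fixture
def active_site():
    return make_active_site(n_waters_near=3, n_waters_far=2, plant_hbond=True, seed=42)


@pytest.fixture(scope="session")
def bche_adducts():
    return load_bche_adducts()


@pytest.fixture(scope="session")
def bche_am1_table():
    return load_bche_am1_table()


@pytest.fixture(scope="session")
def bche_mm_table():
    return load_bche_mm_table()


@pytest.fixture(scope="session")
def cbdp_poses():
    return load_cbdp_docking_poses()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
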