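import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hostlattice import (
    UnitCell, build_ideal_helix, make_toy_crystal,
)

MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 20.00"
    "           C  \nEND\n"
)

CRYST1_PDB = (
    "CRYST1  192.690  192.690  123.940  90.00  90.00 120.00 P 65\n"
    "ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00 30.00"
    "           N  \n"
    "ATOM      2  CA  ALA A   1      11.458  10.000  10.000  1.00 31.00"
    "           C  \n"
    "ATOM      3  C   ALA A   1      12.000  11.400  10.000  1.00 32.00"
    "           C  \n"
    "END\n"
)


@pytest.fixture(scope="session")
def table2_cell():
    """The host crystal's hexagonal cell (Å, degrees)."""
    return UnitCell(192.69, 192.69, 123.94, 90.0, 90.0, 120.0)


@pytest.fixture(scope="session")
def toy_p65():
    return make_toy_crystal("P 65", UnitCell(40, 40, 30, 90, 90, 120),
                            n_res=8, seed=7)


@pytest.fixture(scope="session")
def toy_p1():
    return make_toy_crystal("P 1", UnitCell(30, 30, 30), n_res=10, seed=3)


@pytest.fixture(scope="session")
def helix18():
    return build_ideal_helix(18)


@pytest.fixture(scope="session")
def helix_ca18(helix18):
    return np.array([r.atom("CA").xyz for r in helix18.residues])
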