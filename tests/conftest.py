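"""Shared fixtures: synthetic structures and small PDB/annotation files."""

import numpy as np
import pytest

from cutofflens import (
    make_dimer,
    make_globule,
    make_helix,
    make_planted_hub,
)


@pytest.fixture(scope="session")
def helix10():
    return make_helix(10)


@pytest.fixture(scope="session")
def globule40():
    """Connected, non-collinear compact chain (N=40, fixed seed)."""
    return make_globule(40, seed=7, envelope_radius=12.0)


@pytest.fixture(scope="session")
def planted_hub():
    """(structure, annotation, hub indices) with the default study conditions."""
    return make_planted_hub(seed=0)


@pytest.fixture(scope="session")
def dimer30():
    return make_dimer(30, seed=3)


MINIMAL_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   3       7.600   0.000   0.000  1.00  0.00           C
TER
END
"""

PDB_WITH_HETATM = MINIMAL_PDB.replace(
    "TER\nEND\n",
    "HETATM    4  CA  CA  A 201      20.000  20.000  20.000  1.00  0.00          CA\n"
    "TER\nEND\n",
)

PDB_WITH_ALTLOC = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def hetatm_pdb(tmp_path):
    p = tmp_path / "het.pdb"
    p.write_text(PDB_WITH_HETATM)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(PDB_WITH_ALTLOC)
    return p


def random_point_structure(n, seed, box=30.0):
    """Random (non-chain) point cloud wrapped as a CAStructure."""
    from cutofflens.structures import CAStructure, Residue

    rng = np.random.Generator(np.random.PCG64(seed))
    coords = np.round(rng.random((n, 3)) * box, 3)
    return CAStructure(
        structure_id=f"rand-{seed}",
        residues=[Residue("A", i + 1, "", tuple(c)) for i, c in enumerate(coords)],
    )
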