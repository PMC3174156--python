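"""Shared fixtures: synthetic structures, hand-written PDB snippets, and one
session-scoped docking batch reused by the scoring/evaluation tests."""

import numpy as np
import pytest

from bindlev import elastic_modes, fixtures, probe_docking, structure_io

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.599   5.500  -4.195  1.00  0.00           C
ATOM      4  CA  GLY A   2      12.200   9.500  -4.000  1.00  0.00           C
ATOM      5  CA  SER A   3      14.800  11.000  -2.500  1.00  0.00           C
TER
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
TER
ATOM      4  CA  ALA B   1       0.000  10.000   0.000  1.00  0.00           C
ATOM      5  CA  GLY B   2       3.800  10.000   0.000  1.00  0.00           C
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   2.000   3.000  0.60  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       4.800   2.000   3.000  1.00  0.00           C
TER
END
"""

LIGAND_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
TER
HETATM    3  PA  AP5 A 101       2.000   3.000   0.000  1.00  0.00           P
HETATM    4  PB  AP5 A 101       3.000   4.000   0.000  1.00  0.00           P
HETATM    5  O   HOH A 201       8.000   8.000   8.000  1.00  0.00           O
HETATM    6  S   SAM A 102       1.000   5.000   0.000  1.00  0.00           S
HETATM    7  S   SAM B 102       1.000   7.000   0.000  1.00  0.00           S
END
"""


@pytest.fixture(scope="session")
def hinge():
    """(open, closed, pocket_truth) hinge fixture shared across the session."""
    return fixtures.make_hinge_protein(seed=1)


@pytest.fixture(scope="session")
def hinge_modes(hinge):
    open_s, _, _ = hinge
    return elastic_modes.build_modes(open_s)


@pytest.fixture(scope="session")
def hinge_dx(hinge):
    open_s, closed_s, _ = hinge
    return structure_io.difference_vector(open_s, closed_s)


@pytest.fixture(scope="session")
def hinge_locations(hinge):
    """A modest docking batch on the open hinge, reused by scoring tests."""
    open_s, _, _ = hinge
    config = probe_docking.SimulationConfig(
        probe_size=4, n_sims=120, n_steps=30_000, seed=7
    )
    return probe_docking.generate_probe_locations(open_s, config)


@pytest.fixture(scope="session")
def decoy():
    return fixtures.make_decoy_with_planted_pocket(60, 4.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
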