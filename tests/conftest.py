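"""Shared fixtures: small synthetic systems with known ground truth."""

import numpy as np
import pytest

from confshift.model_io import RegionSet, Trajectory
from confshift.synthetic_data import bead_topology


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_bead_trajectory(coords_per_frame, bead_radius=0.3):
    """Trajectory over a one-bead-per-residue topology from a frame list."""
    frames = np.asarray(coords_per_frame, dtype=float)
    top = bead_topology(frames.shape[1], bead_radius=bead_radius)
    return Trajectory(top, frames)


@pytest.fixture
def bead_trajectory_factory():
    return make_bead_trajectory


@pytest.fixture
def random_walk_trajectory(rng):
    """12 beads, 10 frames of smooth random motion (non-degenerate)."""
    base = rng.normal(size=(12, 3))
    frames = base + 0.08 * rng.normal(size=(10, 12, 3)).cumsum(axis=0)
    return make_bead_trajectory(frames)


@pytest.fixture
def two_state_trajectory(rng):
    """20 frames: 10 near one anchor, 10 near a distant second anchor."""
    a = rng.normal(size=(8, 3))
    b = a + np.array([4.0, 0.0, 0.0]) + rng.normal(size=(8, 3))
    frames = np.concatenate(
        [a + 0.01 * rng.normal(size=(10, 8, 3)),
         b + 0.01 * rng.normal(size=(10, 8, 3))]
    )
    labels = ["A"] * 10 + ["B"] * 10
    return make_bead_trajectory(frames), labels


@pytest.fixture
def simple_regions():
    return RegionSet(
        {"left": frozenset({1, 2, 3}), "right": frozenset({6, 7, 8})}
    )


PDB_TWO_ATOMS = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
END
"""

PDB_THREE_MODELS = """\
MODEL        1
ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       1.100   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.900   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        3
ATOM      1  CA  ALA A   1       1.200   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       5.000   0.000   0.000  1.00  0.00           C
ENDMDL
"""


@pytest.fixture
def pdb_two_atoms():
    return PDB_TWO_ATOMS


@pytest.fixture
def pdb_three_models():
    return PDB_THREE_MODELS
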