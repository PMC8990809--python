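import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pipsites import (
    MembraneFrame,
    SiteDef,
    make_dwell_trajectory,
    make_pose_set,
    make_toy_oligomer,
)


@pytest.fixture(scope="session")
def toy_model():
    """Exactly C4-symmetric toy tetramer, 12 residues per chain."""
    return make_toy_oligomer(n_chains=4, residues_per_chain=12, radius=18.0, seed=1)


@pytest.fixture(scope="session")
def frame():
    return MembraneFrame(midplane_z=0.0, intracellular_boundary_z=-20.0)


@pytest.fixture(scope="session")
def model_radius(toy_model):
    return float(np.max(np.linalg.norm(toy_model.coords[:, :2], axis=1)))


@pytest.fixture()
def two_center_poses(toy_model, model_radius):
    """100 poses around two planted centers 40+ A apart, quarter misoriented."""
    r = model_radius + 4.0
    centers = [
        [r * np.cos(np.radians(20)), r * np.sin(np.radians(20)), -15.0],
        [r * np.cos(np.radians(70)), r * np.sin(np.radians(70)), -10.0],
    ]
    return make_pose_set(
        toy_model, centers, n_per_center=50, scatter_sigma=2.0,
        frac_misoriented=0.25, seed=11,
    )


# planted dwell sites on long-side-chain (LYS/ARG) residues, so scripted
# bead placements clear all neighbouring residues
SITE_A = (("A", 1), ("A", 2), ("A", 7), ("A", 8))
SITE_B = (("B", 1), ("B", 2), ("B", 7))
SITE_NEVER = (("C", 1), ("C", 2))


@pytest.fixture()
def dwell_fixture(toy_model):
    traj, truth = make_dwell_trajectory(
        toy_model,
        [
            SiteDef(residues=SITE_A, occupancy_pct=100.0),
            SiteDef(residues=SITE_B, occupancy_pct=40.0),
            SiteDef(residues=SITE_NEVER, occupancy_pct=0.0),
        ],
        n_frames=500,
        seed=21,
    )
    return traj, truth
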