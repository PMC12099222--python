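"""Shared fixtures: expensive renderings are built once per session."""

import numpy as np
import pytest

from phantomqc import geometry as geo
from phantomqc import simulate as sim


@pytest.fixture(scope="session")
def phantom():
    return geo.PhantomGeometry()


@pytest.fixture(scope="session")
def design(phantom):
    return phantom.fiducials()


@pytest.fixture(scope="session")
def template_pair(phantom):
    """High-resolution noiseless template rendering with labels."""
    return sim.make_template(phantom)


@pytest.fixture(scope="session")
def clean_session(phantom):
    """Noiseless, undistorted, identity-placed QC session."""
    truth = sim.SessionGroundTruth()
    scans, sidecar = sim.simulate_session(geometry=phantom, truth=truth, seed=11)
    return scans, sidecar, truth


@pytest.fixture(scope="session")
def misplaced_session(phantom):
    """Noiseless session with a known rigid misplacement (5 deg, 3/-2/1 mm)."""
    truth = sim.SessionGroundTruth(rotation_deg=(0.0, 0.0, 5.0), translation_mm=(3.0, -2.0, 1.0))
    scans, sidecar = sim.simulate_session(geometry=phantom, truth=truth, seed=12)
    return scans, sidecar, truth


@pytest.fixture(scope="session")
def clean_axial_with_labels(phantom):
    """Noiseless identity axial scan plus ground-truth labels on its grid."""
    seq = sim.t2w_sequence("axial")
    truth = sim.SessionGroundTruth()
    vol, labels = sim.rasterize_phantom(phantom, seq, truth, seed=None, with_labels=True)
    return vol, labels, truth


def design_positions(design):
    return {f.id: np.asarray(f.design_position) for f in design}
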