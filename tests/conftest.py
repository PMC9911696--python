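"""Shared fixtures: phantoms and rendered images are session-scoped since
builds are deterministic and read-only in tests."""
import numpy as np
import pytest

from rnatopo import afm_sim, rna_cg, synthetic_data as sd
from rnatopo.config import FitSchedule


@pytest.fixture(scope="session")
def phantom_spec():
    return sd.PhantomSpec(preset="Y")


@pytest.fixture(scope="session")
def phantom_ss(phantom_spec):
    return sd.secondary_structure(phantom_spec)


@pytest.fixture(scope="session")
def truth_y(phantom_spec):
    return sd.make_phantom(phantom_spec)


@pytest.fixture(scope="session")
def clean_image(truth_y):
    return afm_sim.render_surface(truth_y)


@pytest.fixture(scope="session")
def duplex22():
    return rna_cg.build_aform_helix(22)


@pytest.fixture()
def quick_schedule():
    """Small annealing schedule for optimizer unit tests."""
    return FitSchedule(n_steps=1500, t_start=1.0, t_end=0.02,
                       n_cycles=1, n_polish=500)


@pytest.fixture(scope="session")
def sphere_phantom():
    """1000 beads uniformly filling a sphere of radius 30 A."""
    rng = np.random.default_rng(0)
    R = 30.0
    pts = []
    while len(pts) < 1000:
        x = rng.uniform(-R, R, 3)
        if np.linalg.norm(x) <= R:
            pts.append(x)
    pts = np.array(pts)
    n = len(pts)
    cg = rna_cg.CGStructure(
        coords=pts, nt_index=np.arange(n) // 2, role=np.tile([0, 1], n // 2),
        chain_id=np.zeros(n, int), helix_id=np.full(n, -1),
        bonds=np.empty((0, 2), int))
    cg.radius = R
    return cg
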