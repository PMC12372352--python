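"""Shared fixtures: small deterministic trajectories and the three
session-scoped synthetic study tables (fingerprinted once, reused by the
classification, similarity and acceptance tests)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from diffprint import Trajectory, fingerprint_table
from diffprint.simulate import build_synthetic_study, default_study_design

STUDY_SEED = 7


def make_traj(points, dt=1.0, particle_id="p"):
    pts = np.asarray(points, dtype=float)
    return Trajectory(particle_id=particle_id, frames=np.arange(len(pts)),
                      x=pts[:, 0], y=pts[:, 1], dt=dt)


@pytest.fixture
def straight_traj():
    """101 collinear positions with unit spacing (ballistic motion)."""
    n = 101
    return make_traj(np.column_stack([np.arange(n, dtype=float), np.zeros(n)]))


@pytest.fixture
def right_angle_traj():
    return make_traj([(0.0, 0.0), (3.0, 0.0), (3.0, 4.0)])


def _study_table(kind, n_per_cell):
    design = default_study_design(kind, n_per_cell=n_per_cell)
    trajs, labels = build_synthetic_study(design, seed=STUDY_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fingerprint_table(trajs, labels)


@pytest.fixture(scope="session")
def heterogeneous_table():
    """Overlapping-mixture study: 3 media x 100 trajectories."""
    return _study_table("heterogeneous", 100)


@pytest.fixture(scope="session")
def disjoint_table():
    """Per-medium Brownian diffusivities separated by 100x: trivially separable."""
    return _study_table("disjoint", 60)


@pytest.fixture(scope="session")
def identical_table():
    """All media share one Brownian population: classification is at chance."""
    return _study_table("identical", 80)
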