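"""Shared fixtures.

The two heavy session fixtures reproduce the study conditions at reduced
ensemble size (500 trajectories per grid cell; 5000 for the point-particle
oracle, the full study ensemble size) and are shared by every test that
needs simulation output at scale.
"""
from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from porewalk import (
    Channel,
    SimulationConfig,
    Spherocylinder,
    run_ensemble,
    summarize,
    survival_from_ensemble,
)

GRID_DS = (0.03, 0.45, 0.9)
GRID_FS = (1.0, 2.9, 5.6)
GRID_N_TRAJ = 500
GRID_SEED = 73

POINT_N_TRAJ = 5000
POINT_SEED = 1234


@pytest.fixture(scope="session")
def corner_grid():
    """(d, f) corner-grid ensembles at sigma_x=0.05, L=14.3, 500 trajectories.

    Returns {(d, f): {"fits": summary dict, "fpt": uncensored FPT samples}}.
    Positions are dropped after summarization to keep memory bounded.
    """
    cells = {}
    i = 0
    for d in GRID_DS:
        for f in GRID_FS:
            cfg = SimulationConfig(
                particle=Spherocylinder.from_aspect(f, d),
                channel=Channel(L=14.3),
                sigma_x=0.05,
                seed=GRID_SEED + i,
                n_traj=GRID_N_TRAJ,
            )
            res = run_ensemble(cfg)
            fits = summarize(res)
            fpt = res.fpt_steps
            cells[(d, f)] = {"fits": fits, "fpt": fpt[fpt >= 0].copy()}
            del res
            i += 1
    return cells


@pytest.fixture(scope="session")
def point_particle_ensemble():
    """d=0.03 sphere at the default parameters, 5000 trajectories.

    Positions are effectively not recorded (stride beyond the step cap is
    not allowed, so a very sparse stride is used): only first-passage
    statistics are needed here.
    """
    cfg = SimulationConfig(
        particle=Spherocylinder(l=0.0, d=0.03),
        channel=Channel(L=14.3),
        sigma_x=0.05,
        seed=POINT_SEED,
        n_traj=POINT_N_TRAJ,
        record_stride=1_000_000,
    )
    return run_ensemble(cfg)


@pytest.fixture(scope="session")
def point_particle_survival(point_particle_ensemble):
    return survival_from_ensemble(point_particle_ensemble)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
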