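"""Stochastic update loop and ensemble execution.

The particle performs an overdamped random walk: per step, an isotropic
Gaussian translation attempt (components N(0, sigma_x)) and a rotation
attempt about a uniformly random axis by an angle drawn from
N(0, sigma_phi(A)), where sigma_phi = sigma_x * (A^T M A)^(-1/2) so that the
translational and rotational noise share energy equally (equipartition).
Attempts that would push the capsule into the cylindrical wall, or the
center past the entrance plane z < 0, are rejected and the particle stays
put; time advances by one step regardless.  Reaching z >= L absorbs the
particle and ends the trajectory.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .geometry import (
    Channel,
    ParticleState,
    Spherocylinder,
    axial_moment,
    collides,
    random_unit_axis,
    rotate_axis,
)

DEFAULT_SIGMA_X = 0.05
DEFAULT_L = 14.3
DEFAULT_N_TRAJ = 5000
DEFAULT_RECORD_STRIDE = 100


def default_max_steps(L: float, sigma_x: float) -> int:
    """Safety cap: 100x the 1D mean passage time ``L**2 / sigma_x**2``.

    The FPT tail is exponential, so the censored fraction at this cap is
    astronomically small at the default parameters.
    """
    return max(10_000, int(100.0 * L * L / (sigma_x * sigma_x)))


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one ensemble run (everything needed to replay it)."""

    particle: Spherocylinder
    channel: Channel = field(default_factory=lambda: Channel(L=DEFAULT_L))
    sigma_x: float = DEFAULT_SIGMA_X
    seed: int = 0
    n_traj: int = DEFAULT_N_TRAJ
    max_steps: Optional[int] = None
    record_stride: int = DEFAULT_RECORD_STRIDE

    def __post_init__(self) -> None:
        if not self.sigma_x > 0:
            raise ValueError(f"sigma_x must be > 0, got {self.sigma_x}")
        if self.n_traj < 1:
            raise ValueError(f"n_traj must be >= 1, got {self.n_traj}")
        if self.record_stride < 1:
            raise ValueError(f"record_stride must be >= 1, got {self.record_stride}")
        if self.max_steps is not None and self.max_steps < 1:
            raise ValueError(f"max_steps must be >= 1, got {self.max_steps}")
        # initial state: centered at the entrance, aligned with the pore axis
        if collides(self.particle, np.zeros(3), np.array([0.0, 0.0, 1.0]), self.channel):
            raise ValueError(
                "initial aligned state collides with the wall: d must be < 1"
            )

    @property
    def effective_max_steps(self) -> int:
        if self.max_steps is not None:
            return self.max_steps
        return default_max_steps(self.channel.L, self.sigma_x)

    def subseeds(self) -> np.ndarray:
        """Per-trajectory sub-seeds, deterministically spawned from ``seed``."""
        return np.random.SeedSequence(self.seed).generate_state(self.n_traj, dtype=np.uint32)


@dataclass
class TrajectoryResult:
    """Outcome of a single translocation attempt."""

    fpt: Optional[int]            #: first-passage time in steps; None if censored
    censored: bool
    exit_theta: Optional[float]   #: angle(u, z-axis) at absorption, radians
    positions: np.ndarray         #: (n, 4) rows (t, x, y, z), every record_stride steps
    accepted_translations: int
    accepted_rotations: int
    seed: int


@dataclass
class EnsembleResult:
    """A set of independent trajectories sharing one configuration."""

    config: SimulationConfig
    trajectories: list[TrajectoryResult]

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def fpt_steps(self) -> np.ndarray:
        """First-passage times; censored trajectories carry -1."""
        return np.array(
            [t.fpt if not t.censored else -1 for t in self.trajectories], dtype=np.int64
        )

    @property
    def censored(self) -> np.ndarray:
        return np.array([t.censored for t in self.trajectories], dtype=bool)

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    @property
    def exit_thetas(self) -> np.ndarray:
        """Exit angles of the uncensored trajectories, radians in [0, pi]."""
        return np.array(
            [t.exit_theta for t in self.trajectories if not t.censored], dtype=float
        )

    @property
    def tmin(self) -> int:
        """Minimal observed first-passage time (uncensored)."""
        fpt = self.fpt_steps
        ok = fpt[fpt >= 0]
        if ok.size == 0:
            raise ValueError("all trajectories censored: no first-passage time observed")
        return int(ok.min())

    def durations_events(self) -> tuple[np.ndarray, np.ndarray]:
        """(durations, event flags) for survival estimation; censored
        trajectories contribute max_steps with event=False."""
        fpt = self.fpt_steps.astype(float)
        cens = self.censored
        fpt[cens] = self.config.effective_max_steps
        return fpt, ~cens


def sigma_phi(p: Spherocylinder, u: np.ndarray, A: np.ndarray, sigma_x: float) -> float:
    """Rotational step scale about axis ``A``: sigma_x * (A^T M A)^(-1/2)."""
    return sigma_x / math.sqrt(axial_moment(p, u, A))


def propose_translation(rng: np.random.Generator, sigma_x: float) -> np.ndarray:
    """Isotropic Gaussian displacement, components independent N(0, sigma_x)."""
    return rng.normal(scale=sigma_x, size=3)


def step(state: ParticleState, cfg: SimulationConfig, rng: np.random.Generator) -> ParticleState:
    """One update of the reference (pure-Python) implementation.

    Identical accept/reject logic to the compiled kernel; used for readable
    unit and property tests.  Returns a new state; ``state.t`` advances by
    exactly 1 whether or not either attempt was accepted.
    """
    p, ch = cfg.particle, cfg.channel
    new = state.copy()
    dx = propose_translation(rng, cfg.sigma_x)
    nx = state.x + dx
    if nx[2] >= 0.0 and not collides(p, nx, state.u, ch):
        new.x = nx
    if new.x[2] < ch.L:  # no rotation once absorbed
        A = random_unit_axis(rng)
        dphi = rng.normal() * sigma_phi(p, new.u, A, cfg.sigma_x)
        nu = rotate_axis(new.u, A, dphi)
        if not collides(p, new.x, nu, ch):
            new.u = nu
    new.t = state.t + 1
    return new


def run_trajectory(cfg: SimulationConfig, seed: Optional[int] = None) -> TrajectoryResult:
    """Simulate one trajectory with the compiled kernel.

    ``seed`` defaults to the first sub-seed spawned from ``cfg.seed``; results
    are bit-identical across repeated calls with the same seed.
    """
    if seed is None:
        seed = int(cfg.subseeds()[0])
    p = cfg.particle
    max_steps = cfg.effective_max_steps
    rec = np.empty((max_steps // cfg.record_stride + 1, 4))
    fpt, theta, acc_t, acc_r, n_rec = _kernels.run_capsule_trajectory(
        seed, 0.5 * p.l, p.r, cfg.channel.radius, cfg.channel.L, cfg.sigma_x,
        p.Mxx, p.Mzz, max_steps, cfg.record_stride, rec,
    )
    censored = fpt == _kernels.CENSORED
    return TrajectoryResult(
        fpt=None if censored else int(fpt),
        censored=bool(censored),
        exit_theta=None if censored else float(theta),
        positions=rec[:n_rec].copy(),
        accepted_translations=int(acc_t),
        accepted_rotations=int(acc_r),
        seed=int(seed),
    )


def run_ensemble(cfg: SimulationConfig) -> EnsembleResult:
    """Run ``cfg.n_traj`` independent trajectories serially.

    Sub-seeds come from a numpy SeedSequence spawned from the master seed, so
    the ensemble is reproducible as a whole and per trajectory.
    """
    seeds = cfg.subseeds()
    trajectories = [run_trajectory(cfg, int(s)) for s in seeds]
    return EnsembleResult(config=cfg, trajectories=trajectories)
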