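"""Result serialization: plain CSV + JSON, regenerable from run_meta.json.

A run directory contains:

* ``fpt.csv``      — traj_id, seed, fpt_steps (-1 if censored), exit_theta_rad,
  censored, accepted_translations, accepted_rotations
* ``traj_<id>.csv`` — t, x, y, z at the recording stride (optional)
* ``run_meta.json`` — full configuration echo, package version, counts

Everything needed to regenerate the run bit-identically is in run_meta.json.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import EnsembleResult, SimulationConfig, TrajectoryResult
from .geometry import Channel, Spherocylinder


def config_to_dict(cfg: SimulationConfig) -> dict:
    return {
        "l": cfg.particle.l,
        "d": cfg.particle.d,
        "f": cfg.particle.f,
        "L": cfg.channel.L,
        "sigma_x": cfg.sigma_x,
        "seed": cfg.seed,
        "n_traj": cfg.n_traj,
        "max_steps": cfg.effective_max_steps,
        "record_stride": cfg.record_stride,
    }


def config_from_dict(meta: dict) -> SimulationConfig:
    return SimulationConfig(
        particle=Spherocylinder(l=meta["l"], d=meta["d"]),
        channel=Channel(L=meta["L"]),
        sigma_x=meta["sigma_x"],
        seed=meta["seed"],
        n_traj=meta["n_traj"],
        max_steps=meta["max_steps"],
        record_stride=meta["record_stride"],
    )


def ensemble_frame(res: EnsembleResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "traj_id": np.arange(len(res)),
            "seed": [t.seed for t in res.trajectories],
            "fpt_steps": res.fpt_steps,
            "exit_theta_rad": [
                t.exit_theta if not t.censored else np.nan for t in res.trajectories
            ],
            "censored": res.censored,
            "accepted_translations": [t.accepted_translations for t in res.trajectories],
            "accepted_rotations": [t.accepted_rotations for t in res.trajectories],
        }
    )


def save_run(res: EnsembleResult, outdir: str | Path, trajectories: bool = True) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ensemble_frame(res).to_csv(outdir / "fpt.csv", index=False)
    if trajectories:
        for i, tr in enumerate(res.trajectories):
            pd.DataFrame(tr.positions, columns=["t", "x", "y", "z"]).to_csv(
                outdir / f"traj_{i:05d}.csv", index=False
            )
    meta = {
        "config": config_to_dict(res.config),
        "version": __version__,
        "n_traj": len(res),
        "n_censored": res.n_censored,
        "trajectories_saved": bool(trajectories),
    }
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2))
    return outdir


def load_run(rundir: str | Path) -> EnsembleResult:
    rundir = Path(rundir)
    meta = json.loads((rundir / "run_meta.json").read_text())
    cfg = config_from_dict(meta["config"])
    table = pd.read_csv(rundir / "fpt.csv")
    trajs = []
    for row in table.itertuples(index=False):
        traj_file = rundir / f"traj_{int(row.traj_id):05d}.csv"
        if traj_file.exists():
            positions = pd.read_csv(traj_file).to_numpy(dtype=float)
        else:
            positions = np.empty((0, 4))
        censored = bool(row.censored)
        trajs.append(
            TrajectoryResult(
                fpt=None if censored else int(row.fpt_steps),
                censored=censored,
                exit_theta=None if censored else float(row.exit_theta_rad),
                positions=positions,
                accepted_translations=int(row.accepted_translations),
                accepted_rotations=int(row.accepted_rotations),
                seed=int(row.seed),
            )
        )
    return EnsembleResult(config=cfg, trajectories=trajs)


def write_analysis(rundir: str | Path, msd_curve=None, fits: dict | None = None,
                   angles=None) -> None:
    """Write msd.csv / fits.json / angles.csv into a run directory."""
    rundir = Path(rundir)
    if msd_curve is not None:
        pd.DataFrame(
            {"t": msd_curve.t, "msd": msd_curve.msd, "n_alive": msd_curve.n_alive}
        ).to_csv(rundir / "msd.csv", index=False)
    if fits is not None:
        (rundir / "fits.json").write_text(json.dumps(fits, indent=2))
    if angles is not None:
        pd.DataFrame(
            {
                "bin_center": angles.bin_centers,
                "p_theta": angles.p_theta,
                "p_raw": angles.p_raw,
            }
        ).to_csv(rundir / "angles.csv", index=False)
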