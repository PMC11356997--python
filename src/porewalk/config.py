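"""YAML configuration loading for single runs and (f, d) parameter sweeps."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import (
    DEFAULT_L,
    DEFAULT_N_TRAJ,
    DEFAULT_RECORD_STRIDE,
    DEFAULT_SIGMA_X,
    SimulationConfig,
)
from .geometry import Channel, Spherocylinder


class ConfigError(ValueError):
    """Invalid or incomplete configuration; the message names the field."""


_RUN_KEYS = {"l", "d", "f", "L", "sigma_x", "seed", "n_traj", "max_steps",
             "record_stride"}
_SWEEP_KEYS = {"grid", "pairs", "L", "sigma_x", "seed", "n_traj", "max_steps",
               "record_stride", "out"}


@dataclass
class SweepSpec:
    """A set of (l, d) grid points sharing one simulation template."""

    pairs: list[tuple[float, float]]   #: deduplicated (l, d) pairs
    L: float = DEFAULT_L
    sigma_x: float = DEFAULT_SIGMA_X
    seed: int = 0
    n_traj: int = DEFAULT_N_TRAJ
    max_steps: int | None = None
    record_stride: int = DEFAULT_RECORD_STRIDE
    out: str | None = None

    def cell_config(self, i: int) -> SimulationConfig:
        l, d = self.pairs[i]
        return SimulationConfig(
            particle=Spherocylinder(l=l, d=d),
            channel=Channel(L=self.L),
            sigma_x=self.sigma_x,
            seed=self.seed + i,  # distinct, reproducible per-cell master seeds
            n_traj=self.n_traj,
            max_steps=self.max_steps,
            record_stride=self.record_stride,
        )


def _particle_from(data: dict) -> Spherocylinder:
    if "d" not in data:
        raise ConfigError("missing required field 'd' (particle diameter)")
    d = float(data["d"])
    if not 0 < d < 1:
        raise ConfigError(f"field 'd' must lie in (0, 1), got {d}")
    if "l" in data and "f" in data:
        raise ConfigError("give either 'l' or 'f', not both")
    if "f" in data:
        f = float(data["f"])
        if f < 1:
            raise ConfigError(f"field 'f' must be >= 1, got {f}")
        return Spherocylinder.from_aspect(f, d)
    l = float(data.get("l", 0.0))
    if l < 0:
        raise ConfigError(f"field 'l' must be >= 0, got {l}")
    return Spherocylinder(l=l, d=d)


def _common(data: dict) -> dict:
    if "seed" not in data:
        raise ConfigError("missing required field 'seed' (runs must be reproducible)")
    sigma_x = float(data.get("sigma_x", DEFAULT_SIGMA_X))
    if sigma_x <= 0:
        raise ConfigError(f"field 'sigma_x' must be > 0, got {sigma_x}")
    return {
        "L": float(data.get("L", DEFAULT_L)),
        "sigma_x": sigma_x,
        "seed": int(data["seed"]),
        "n_traj": int(data.get("n_traj", DEFAULT_N_TRAJ)),
        "max_steps": None if data.get("max_steps") is None else int(data["max_steps"]),
        "record_stride": int(data.get("record_stride", DEFAULT_RECORD_STRIDE)),
    }


def _dedup(pairs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    seen, out = set(), []
    for p in pairs:
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


def load_config(path: str | Path) -> SimulationConfig | SweepSpec:
    """Load a YAML config; returns a sweep when 'grid' or 'pairs' is present.

    Unknown keys are errors; 'seed' is always required.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    is_sweep = "grid" in data or "pairs" in data
    allowed = _SWEEP_KEYS if is_sweep else _RUN_KEYS
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if is_sweep:
        common = _common(data)
        pairs: list[tuple[float, float]] = []
        if "pairs" in data:
            for item in data["pairs"]:
                l, d = float(item[0]), float(item[1])
                pairs.append((l, d))
        if "grid" in data:
            grid = data["grid"]
            ds = [float(v) for v in grid.get("d", [])]
            fs = [float(v) for v in grid.get("f", [])]
            if not ds or not fs:
                raise ConfigError("field 'grid' needs non-empty 'd' and 'f' lists")
            for d in ds:
                for f in fs:
                    pairs.append((d * (f - 1.0), d))
        for l, d in pairs:
            if not 0 < d < 1:
                raise ConfigError(f"field 'd' must lie in (0, 1), got {d}")
            if l < 0:
                raise ConfigError(f"field 'l' must be >= 0, got {l}")
        return SweepSpec(pairs=_dedup(pairs), out=data.get("out"), **common)
    common = _common(data)
    particle = _particle_from(data)
    return SimulationConfig(
        particle=particle,
        channel=Channel(L=common.pop("L")),
        **common,
    )
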