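"""Configuration files, CSV series output and run manifests.

Configurations are YAML with a flat, validated schema; every key is
optional and the defaults reproduce the main square-field experiment
(square of side 50, trap radius 5, 10^4 walkers, 1000 steps, 30
replicates)::

    arena:
      shape: square        # or circle
      L: 50.0              # side (square) or radius (circle)
      R: 5.0               # trap radius
    N0: 10000
    steps: 1000
    replicates: 30
    seed: 0
    response:
      r: {preset: "r1/row1"}     # or {constant: 0.5}
                                 # or {family: r2, a: 1.0, b: 1.0}
      s: {preset: "s1"}          # or {constant: 1.0}
                                 # or {family: s4, c: 10, h: 5, d_max: 22.5}

Series are written as long-format CSV (columns ``replicate, step, caught,
cumulative, remaining``) with a JSON manifest sidecar recording the config
echo, master seed, per-replicate seeds, package version and wall time —
enough to reproduce any output bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .movement import TrapArena
from .response import ResponseProfile, RParams, SParams, get_preset
from .simulate import (
    EnsembleResult,
    SimulationConfig,
    TrapCountSeries,
    replicate_seeds,
)

__all__ = [
    "RunManifest",
    "load_config",
    "config_to_dict",
    "write_series_csv",
    "read_series_csv",
]

_TOP_KEYS = {"arena", "N0", "steps", "replicates", "seed", "response"}
_ARENA_KEYS = {"shape", "L", "R"}
_RESP_KEYS = {"r", "s"}


@dataclass
class RunManifest:
    """Reproducibility sidecar written next to every output file."""

    config: dict
    master_seed: int
    replicate_seed_entropy: list[int]
    version: str
    wall_time_s: float
    outputs: list[str]

    def write(self, path: str | Path) -> None:
        payload = vars(self).copy()
        payload["config_hash"] = hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()
        ).hexdigest()[:16]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _validation_error(msg: str) -> ValueError:
    return ValueError(f"invalid configuration: {msg}")


def _build_spec(node, kind: str, R: float):
    """Turn a config mapping into an R/S spec (params object or constant)."""
    if not isinstance(node, dict):
        raise _validation_error(f"response.{kind} must be a mapping")
    keys = set(node)
    if keys == {"preset"}:
        spec = get_preset(node["preset"], R=R)
        expect = RParams if kind == "r" else SParams
        if not isinstance(spec, expect):
            raise _validation_error(
                f"preset {node['preset']!r} is not an {kind}-family preset"
            )
        return spec
    if keys == {"constant"}:
        value = float(node["constant"])
        if value <= 0:
            raise _validation_error(f"constant {kind} must be positive")
        return value
    if "family" in keys:
        family = node["family"]
        fams = ("r1", "r2", "r3", "r4") if kind == "r" else ("s1", "s2", "s3", "s4")
        if family not in fams:
            raise _validation_error(
                f"unknown {kind} family {family!r}; expected one of {', '.join(fams)}"
            )
        params = {k: float(v) for k, v in node.items() if k != "family"}
        try:
            if kind == "r":
                return RParams(family, **params)
            return SParams(family, **params)
        except (TypeError, ValueError) as exc:
            raise _validation_error(f"bad {family} parameters: {exc}") from None
    raise _validation_error(
        f"response.{kind} must give exactly one of: preset, constant, family+params"
    )


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration, filling defaults.

    Unknown keys, non-positive sizes and unknown preset/family names raise
    descriptive :class:`ValueError`.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise _validation_error("top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise _validation_error(
            f"unknown keys {sorted(unknown)}; allowed: {sorted(_TOP_KEYS)}"
        )

    arena_raw = raw.get("arena", {}) or {}
    unknown = set(arena_raw) - _ARENA_KEYS
    if unknown:
        raise _validation_error(f"unknown arena keys {sorted(unknown)}")
    shape = arena_raw.get("shape", "square")
    L = float(arena_raw.get("L", 50.0))
    R = float(arena_raw.get("R", 5.0))
    try:
        arena = TrapArena(shape, extent=L, trap_radius=R)
    except ValueError as exc:
        raise _validation_error(str(exc)) from None

    resp_raw = raw.get("response", {}) or {}
    unknown = set(resp_raw) - _RESP_KEYS
    if unknown:
        raise _validation_error(f"unknown response keys {sorted(unknown)}")
    r_spec = _build_spec(resp_raw.get("r", {"preset": "r1/row1"}), "r", R)
    s_spec = _build_spec(resp_raw.get("s", {"preset": "s1"}), "s", R)
    profile = ResponseProfile(r_spec, s_spec)

    N0 = int(raw.get("N0", 10_000))
    steps = int(raw.get("steps", 1000))
    replicates = int(raw.get("replicates", 30))
    seed = int(raw.get("seed", 0))
    try:
        return SimulationConfig(
            arena=arena,
            profile=profile,
            N0=N0,
            n_steps=steps,
            n_replicates=replicates,
            seed=seed,
        )
    except ValueError as exc:
        raise _validation_error(str(exc)) from None


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serialisable echo of a configuration, for manifests."""
    return {
        "arena": {
            "shape": config.arena.shape,
            "L": config.arena.extent,
            "R": config.arena.trap_radius,
            "trap_center": list(config.arena.trap_center),
        },
        "response": config.profile.describe(),
        "N0": config.N0,
        "steps": config.n_steps,
        "replicates": config.n_replicates,
        "seed": config.seed,
    }


def _series_frame(T: np.ndarray, N0: int, replicate: int) -> pd.DataFrame:
    C = np.cumsum(T)
    return pd.DataFrame(
        {
            "replicate": replicate,
            "step": np.arange(1, len(T) + 1),
            "caught": T,
            "cumulative": C,
            "remaining": N0 - C,
        }
    )


def write_series_csv(
    result: TrapCountSeries | EnsembleResult,
    path: str | Path,
    config: SimulationConfig | None = None,
    wall_time_s: float = 0.0,
) -> Path:
    """Write a series or ensemble as long-format CSV plus a JSON manifest.

    The manifest sidecar is ``<path>.manifest.json``.  Round-trips
    losslessly through :func:`read_series_csv`.
    """
    path = Path(path)
    if isinstance(result, EnsembleResult):
        frames = [
            _series_frame(result.T[i], result.config.N0, i)
            for i in range(result.n_replicates)
        ]
        df = pd.concat(frames, ignore_index=True)
        config = config or result.config
        seed_entropy = result.seeds
    else:
        df = _series_frame(result.T, result.N0, 0)
        seed_entropy = (
            [int(s.entropy) for s in replicate_seeds(config.seed, 1)] if config else []
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if config is not None:
        manifest = RunManifest(
            config=config_to_dict(config),
            master_seed=config.seed,
            replicate_seed_entropy=seed_entropy,
            version=__version__,
            wall_time_s=round(wall_time_s, 3),
            outputs=[str(path)],
        )
        manifest.write(path.with_name(path.name + ".manifest.json"))
    return path


def read_series_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format series CSV back into a DataFrame."""
    df = pd.read_csv(path)
    expected = ["replicate", "step", "caught", "cumulative", "remaining"]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected columns {list(df.columns)}; expected {expected}")
    return df


def series_matrix(df: pd.DataFrame) -> np.ndarray:
    """Pivot a long-format frame to the replicate × step count matrix."""
    wide = df.pivot(index="replicate", columns="step", values="caught")
    return wide.to_numpy()
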