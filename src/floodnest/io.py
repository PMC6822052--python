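"""Configuration parsing and result serialization.

Configs are flat YAML/JSON mappings mirroring the simulation parameters;
omitted fields take the baseline-model defaults (n0 = K = 5000, m = 0.001,
m_size = 0.05, h = 0.4, c = 5, 2000 generations).  Results are written as
plain CSV tables plus a JSON run manifest from which any table can be
regenerated.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .abm import EnvironmentRegime, LifeHistory, ReplicateResult, SimulationConfig
from .experiments import ClimateChangeSpec, SweepGrid


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


_SIM_KEYS = {
    "p", "s", "h", "flood_height_sd",
    "n", "c", "overlap", "adult_survival", "adult_mortality",
    "n0", "k", "m", "m_size", "generations", "seed",
}
_GRID_KEYS = {"p_values", "s_values", "n_values", "replicates", "base_config"}
_CLIMATE_KEYS = {"target", "delta", "change_generation", "followup_generations"}


def simulation_config_from_dict(data: dict) -> SimulationConfig:
    """Build a validated SimulationConfig from a flat mapping."""
    unknown = set(data) - _SIM_KEYS
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    try:
        regime = EnvironmentRegime(
            p=float(data.get("p", 0.1)),
            s=float(data.get("s", 1.0)),
            h=float(data.get("h", 0.4)),
            flood_height_sd=(
                float(data["flood_height_sd"])
                if data.get("flood_height_sd") is not None
                else None
            ),
        )
        life_history = LifeHistory(
            n=int(data.get("n", 1)),
            c=float(data.get("c", 5.0)),
            overlap=bool(data.get("overlap", False)),
            adult_survival=float(data.get("adult_survival", 0.5)),
            adult_mortality=bool(data.get("adult_mortality", False)),
        )
        return SimulationConfig(
            regime=regime,
            life_history=life_history,
            n0=int(data.get("n0", 5000)),
            k=int(data.get("k", 5000)),
            m=float(data.get("m", 0.001)),
            m_size=float(data.get("m_size", 0.05)),
            generations=int(data.get("generations", 2000)),
            seed=(int(data["seed"]) if data.get("seed") is not None else None),
        )
    except ValueError as err:
        raise ConfigError(str(err)) from err


def simulation_config_to_dict(config: SimulationConfig) -> dict:
    """Flat mapping that round-trips through
    :func:`simulation_config_from_dict`."""
    return {
        "p": config.regime.p,
        "s": config.regime.s,
        "h": config.regime.h,
        "flood_height_sd": config.regime.flood_height_sd,
        "n": config.life_history.n,
        "c": config.life_history.c,
        "overlap": config.life_history.overlap,
        "adult_survival": config.life_history.adult_survival,
        "adult_mortality": config.life_history.adult_mortality,
        "n0": config.n0,
        "k": config.k,
        "m": config.m,
        "m_size": config.m_size,
        "generations": config.generations,
        "seed": config.seed,
    }


def sweep_grid_from_dict(data: dict) -> SweepGrid:
    unknown = set(data) - _GRID_KEYS
    if unknown:
        raise ConfigError(f"unknown sweep field(s): {sorted(unknown)}")
    base = simulation_config_from_dict(data.get("base_config", {}) or {})
    kwargs = {"base_config": base}
    for key in ("p_values", "s_values", "n_values"):
        if key in data:
            kwargs[key] = tuple(data[key])
    if "replicates" in data:
        kwargs["replicates"] = int(data["replicates"])
    try:
        return SweepGrid(**kwargs)
    except ValueError as err:
        raise ConfigError(str(err)) from err


def climate_spec_from_dict(data: dict) -> ClimateChangeSpec:
    unknown = set(data) - _CLIMATE_KEYS
    if unknown:
        raise ConfigError(f"unknown climate field(s): {sorted(unknown)}")
    try:
        return ClimateChangeSpec(
            target=data["target"],
            delta=float(data.get("delta", 0.1)),
            change_generation=int(data.get("change_generation", 2000)),
            followup_generations=int(data.get("followup_generations", 200)),
        )
    except KeyError as err:
        raise ConfigError("climate config requires a 'target' field") from err
    except ValueError as err:
        raise ConfigError(str(err)) from err


def load_config(
    path: Union[str, Path]
) -> Union[SimulationConfig, SweepGrid, ClimateChangeSpec]:
    """Load a YAML/JSON config file, dispatching on its fields.

    A mapping with a ``target`` field is a climate-change spec; one with any
    of ``p_values``/``s_values``/``n_values``/``replicates`` is a sweep
    grid; anything else is a single-replicate simulation config.  An empty
    file yields the full baseline-default SimulationConfig.
    """
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    if "target" in data:
        return climate_spec_from_dict(data)
    if _GRID_KEYS & set(data):
        return sweep_grid_from_dict(data)
    return simulation_config_from_dict(data)


def dump_config(config: SimulationConfig, path: Union[str, Path]) -> None:
    """Write a SimulationConfig back to YAML (inverse of load_config)."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(simulation_config_to_dict(config), fh, sort_keys=True)


@dataclass
class RunManifest:
    """What was run and where the outputs landed; round-trips through JSON."""

    command: str
    config: dict
    seeds: list[int]
    outputs: dict[str, str]
    version: str = __version__
    created: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def trajectories_frame(results: list[ReplicateResult]) -> pd.DataFrame:
    """Stack per-replicate trajectories into one long-format table."""
    frames = []
    for i, res in enumerate(results):
        frame = res.trajectory()
        frame.insert(0, "replicate", i)
        frame.insert(1, "seed", res.seed)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["replicate", "seed", "generation", "mean_z", "sd_z", "pop_size"]
        )
    return pd.concat(frames, ignore_index=True)


def write_results(
    summary: pd.DataFrame,
    replicates: Optional[pd.DataFrame],
    out_dir: Union[str, Path],
    *,
    command: str = "run",
    config: Optional[dict] = None,
    trajectories: Optional[list[ReplicateResult]] = None,
    seeds: Optional[list[int]] = None,
) -> RunManifest:
    """Write CSV tables plus a JSON manifest into ``out_dir``.

    Column order is deterministic and floats keep full repr precision, so
    re-running with identical inputs reproduces the CSVs byte for byte
    (the manifest carries a timestamp and is exempt).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        frame.to_csv(path, index=False)
        outputs[name.removesuffix(".csv")] = str(path)

    _write(summary, "summary.csv")
    if replicates is not None:
        _write(replicates, "replicates.csv")
    if trajectories is not None:
        _write(trajectories_frame(trajectories), "trajectories.csv")
    manifest = RunManifest(
        command=command,
        config=config or {},
        seeds=seeds or [],
        outputs=outputs,
    )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(manifest.to_json() + "\n")
    outputs["manifest"] = str(manifest_path)
    return manifest
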