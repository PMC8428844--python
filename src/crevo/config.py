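"""Scenario configuration: schema-validated TOML/JSON configs, bundled
presets, and structured result output."""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .chemostat import IntegrationControl
from .core import EnvironmentSpec, TradeoffSpec
from .dilution import DilutionProtocol
from .evolve import EvolutionParams, EvolutionTrajectory
from .observe import ClusterSummary, simplex_coordinates

__all__ = [
    "ScenarioConfig",
    "ConfigError",
    "load_config",
    "list_presets",
    "load_preset",
    "write_outputs",
]


class ConfigError(ValueError):
    """Config parse/validation failure; message names the offending key."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TradeoffConfig(_Strict):
    gamma: Union[float, list[float]]
    budget: float = 1.0


class EnvironmentConfig(_Strict):
    supply: list[float]
    monod_k: Union[float, list[float]] = 1.0
    decay: Union[float, list[float]] = 0.1
    death_rate: float = 0.25
    uptake_exponent: Union[float, list[float]] = 1.0


class DilutionConfig(_Strict):
    rho0: float = 1e-3
    c_init: Union[float, list[float]] = 1.0
    c_fin: float = 1e-8
    n_batches: int = 1


class EvolutionConfig(_Strict):
    mutation_sigma: float = 0.02
    mutations_per_epoch: int = 3
    epoch_duration: float = 100.0
    epoch_batches: int = 2
    mutant_fraction: float = 0.02
    max_epochs: int = 4000
    stop_window: int = 300
    stop_mean_tol: float = 0.005
    stop_var_rel_tol: float = 0.25
    stop_var_abs_tol: float = 5e-4
    cluster_cutoff: float = 0.2
    merge_distance: Optional[float] = None


class ControlConfig(_Strict):
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_time: float = 1e6
    extinction_threshold: Optional[float] = None  # None -> 1e-6 * sum(s)/delta
    checkpoint_interval: float = 10.0


class ScenarioConfig(_Strict):
    """Fully-resolved description of one run."""

    mode: Literal["chemostat", "dilution"] = "chemostat"
    tradeoff: TradeoffConfig
    environment: EnvironmentConfig
    dilution: Optional[DilutionConfig] = None
    evolution: Optional[EvolutionConfig] = None
    control: ControlConfig = Field(default_factory=ControlConfig)
    seed: int = 0

    def tradeoff_spec(self) -> TradeoffSpec:
        return TradeoffSpec(gamma=self.tradeoff.gamma, budget=self.tradeoff.budget)

    def environment_spec(self) -> EnvironmentSpec:
        e = self.environment
        return EnvironmentSpec(
            supply=e.supply,
            monod_K=e.monod_k,
            decay=e.decay,
            death_rate=e.death_rate,
            uptake_exponent=e.uptake_exponent,
        )

    def dilution_protocol(self) -> DilutionProtocol:
        if self.dilution is None:
            raise ConfigError("dilution: section required for mode='dilution'")
        d = self.dilution
        p = len(self.environment.supply)
        c0 = d.c_init if isinstance(d.c_init, list) else [d.c_init] * p
        return DilutionProtocol(
            rho0=d.rho0, c_init=c0, c_fin=d.c_fin, n_batches=d.n_batches
        )

    def evolution_params(self) -> EvolutionParams:
        ev = self.evolution or EvolutionConfig()
        return EvolutionParams(rng_seed=self.seed, **ev.model_dump())

    def integration_control(self) -> IntegrationControl:
        c = self.control
        thr = c.extinction_threshold
        if thr is None:
            env = self.environment
            scale = (
                sum(env.supply) / env.death_rate if env.death_rate > 0 else 1.0
            )
            thr = 1e-6 * scale
        return IntegrationControl(
            rel_tol=c.rel_tol,
            abs_tol=c.abs_tol,
            max_time=c.max_time,
            extinction_threshold=thr,
            checkpoint_interval=c.checkpoint_interval,
        )


def _validation_message(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(x) for x in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a TOML or JSON scenario config.

    Unknown keys are rejected; validation errors name the offending key
    path.
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
        if path.suffix.lower() == ".json":
            data = json.loads(raw)
        else:
            data = tomllib.loads(raw.decode())
    except (OSError, ValueError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return validate_config(data)


def validate_config(data: dict) -> ScenarioConfig:
    try:
        return ScenarioConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(_validation_message(exc)) from exc


def list_presets() -> list[str]:
    """Names of the bundled scenario presets."""
    root = resources.files("crevo") / "presets"
    return sorted(f.name[: -len(".toml")] for f in root.iterdir() if f.name.endswith(".toml"))


def load_preset(name: str) -> ScenarioConfig:
    root = resources.files("crevo") / "presets"
    f = root / f"{name}.toml"
    if not f.is_file():
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}"
        )
    return validate_config(tomllib.loads(f.read_text()))


def write_outputs(
    result: Union[EvolutionTrajectory, ClusterSummary],
    config: ScenarioConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write structured results: strain trajectory CSV, cluster summary
    JSON, event log (line-delimited JSON), and the fully-resolved config.

    Floats are serialized with Python's shortest round-trip repr, so
    re-reading the CSV reproduces the trajectory bitwise.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.tradeoff_spec()
    written: dict[str, Path] = {}

    if isinstance(result, EvolutionTrajectory):
        rows = []
        for snap in result.snapshots:
            for sid, (ph, n) in enumerate(snap.strains):
                x = simplex_coordinates(ph, spec)
                row = {"time": snap.time, "strain_id": sid}
                row.update({f"alpha_{j+1}": ph.alpha[j] for j in range(ph.p)})
                row.update({f"x_{j+1}": x[j] for j in range(ph.p)})
                row["density"] = n
                rows.append(row)
        cols = (
            list(rows[0].keys())
            if rows
            else ["time", "strain_id", "density"]
        )
        traj_path = outdir / "trajectory.csv"
        pd.DataFrame(rows, columns=cols).to_csv(traj_path, index=False)
        written["trajectory"] = traj_path

        events_path = outdir / "events.ndjson"
        with events_path.open("w") as fh:
            for ev in result.events:
                fh.write(json.dumps(ev) + "\n")
        written["events"] = events_path
    else:
        clusters_path = outdir / "clusters.json"
        payload = {
            "linkage_cutoff": result.linkage_cutoff,
            "clusters": [
                {
                    "center": c.center.tolist(),
                    "simplex": simplex_coordinates(c.center, spec).tolist(),
                    "total_density": c.total_density,
                    "n_strains": c.n_strains,
                    "is_specialist": c.is_specialist,
                    "specialist_resource": c.specialist_resource,
                }
                for c in result.clusters
            ],
        }
        clusters_path.write_text(json.dumps(payload, indent=2))
        written["clusters"] = clusters_path

    cfg_path = outdir / "config.json"
    cfg_path.write_text(config.model_dump_json(indent=2))
    written["config"] = cfg_path
    return written
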