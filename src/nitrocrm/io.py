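"""Run configuration and tabular exports.

A run is fully described by a flat, serializable :class:`RunConfig`
(trait source, dilution, supply or grid, subsystem, solver settings).
Config files are YAML (or JSON, a YAML subset); command-line flags
override file values field by field.  Every run archives its resolved
config beside its outputs so results are reproducible from the sidecar
alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import EquilibriumResult
from .model import SupplySpec
from .traits import (
    DEFAULT_DILUTION,
    RESOURCES,
    TYPES,
    TraitSet,
    builtin_trait_fixture,
    load_trait_table,
)

__all__ = [
    "RunConfig",
    "load_config",
    "resolve_traits",
    "resolve_supply",
    "trajectory_frame",
    "equilibrium_summary",
]


@dataclass
class RunConfig:
    traits: str = "builtin"            # "builtin" or a trait CSV path
    dilution: float = DEFAULT_DILUTION
    supply: list = field(default_factory=lambda: [1.0, 30.0, 0.0, 0.0, 0.0])
    subsystem: list = field(default_factory=lambda: list(TYPES))
    grid: list = field(default_factory=lambda: [61, 61])
    s1_range: list = field(default_factory=lambda: [0.05, 30.0])
    s2_range: list = field(default_factory=lambda: [0.05, 30.0])
    spacing: str = "log"  # supply-axis spacing: "log" or "linear"
    max_horizon: float = 1e6
    residual_tol: float = 1e-8
    rtol: float = 1e-8
    atol: float = 1e-12
    seed: int = 0
    outdir: str = "."

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus overrides.

    Overrides with value ``None`` are ignored, so CLI flags can be passed
    through unconditionally.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(RunConfig)}
        if unknown:
            raise ValueError(f"config {path}: unknown field(s) {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def resolve_traits(cfg: RunConfig) -> TraitSet:
    if cfg.traits == "builtin":
        return builtin_trait_fixture(dilution=cfg.dilution)
    return load_trait_table(cfg.traits, dilution=cfg.dilution)


def resolve_supply(cfg: RunConfig) -> SupplySpec:
    s = np.zeros(5)
    s[: len(cfg.supply)] = cfg.supply
    return SupplySpec(s)


def trajectory_frame(times: np.ndarray, states: np.ndarray) -> pd.DataFrame:
    """Long-format trajectory table: (time, variable, value)."""
    names = list(TYPES) + list(RESOURCES)
    rows = []
    for k, name in enumerate(names):
        rows.append(pd.DataFrame({"time": times, "variable": name, "value": states[:, k]}))
    return pd.concat(rows, ignore_index=True)


def equilibrium_summary(eq: EquilibriumResult) -> pd.DataFrame:
    """One-row summary of an equilibrium run."""
    row: dict = {
        "converged": eq.converged,
        "t_final": eq.t_final,
        "residual": eq.residual,
        "community": "+".join(sorted(eq.persistent_set)) or "none",
        "N2_flux": eq.fluxes.gas_n2,
        "N2O_production": eq.fluxes.gas_n2o_prod,
        "N2O_consumption": eq.fluxes.gas_n2o_cons,
    }
    for i, tp in enumerate(TYPES):
        row[f"B_{tp}"] = eq.state.B[i]
    for j, r in enumerate(RESOURCES):
        row[f"R_{r}"] = eq.state.R[j]
    for tp, r in eq.limiting.items():
        row[f"limiting_{tp}"] = r
    return pd.DataFrame([row])
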