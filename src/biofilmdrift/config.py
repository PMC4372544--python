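"""Run configuration: JSON files in, validated :class:`RunConfig` out.

A configuration fully specifies one simulation batch: engine, taxa, initial
and source compositions, selection vectors, migration/sloughing parameters,
horizon, replicate count, seed and output options.  Every field has a
default matching the standard three-group study conditions (f = (0.2, 0.8, 0),
p = (0, 0, 1), m = 0.04, N = 10^3), so ``{}`` is a valid (neutral, discrete)
configuration.  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    ConfigError,
    ContinuousParams,
    DiscreteState,
    MigrationParams,
    SelectionParams,
    StateError,
    ParameterError,
    TaxonSet,
    as_composition,
)

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    engine: str = "discrete"
    labels: tuple = ("buffer", "bulk", "biofilm")
    f: tuple = (0.2, 0.8, 0.0)
    p: tuple = (0.0, 0.0, 1.0)
    alpha: tuple = (0.0, 0.0, 0.0)
    beta: tuple = (0.0, 0.0, 0.0)
    N: int = 1000
    m: float = 0.04
    s: float = 0.0
    N_s: int = 0
    p_die: float = 0.0
    n_events: int = 300_000
    t_end: float = 0.3
    dt: float = 1e-5
    boundary_eps: float = 1e-8
    n_runs: int = 1
    seed: int = 0
    record_every: int = 100
    window_start_fraction: float = 0.5
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.engine not in ("discrete", "continuous"):
            raise ConfigError("engine: must be 'discrete' or 'continuous'")
        for name in ("labels", "f", "p", "alpha", "beta"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        r = len(self.labels)
        for name in ("f", "p", "alpha", "beta"):
            if len(getattr(self, name)) != r:
                raise ConfigError(f"{name}: expected length {r} to match labels")
        try:
            self.taxa  # validates labels
            as_composition(self.f, name="f")
            as_composition(self.p, name="p")
            self.selection  # validates alpha/beta
            self.migration  # validates m, s, N_s, p_die and m + s <= 1
        except (StateError, ParameterError) as exc:
            raise ConfigError(str(exc)) from exc
        if self.N < 1:
            raise ConfigError("N: must be >= 1")
        if self.n_events < 0:
            raise ConfigError("n_events: must be >= 0")
        if self.n_runs < 1:
            raise ConfigError("n_runs: must be >= 1")
        if self.record_every < 1:
            raise ConfigError("record_every: must be >= 1")
        if not 0.0 <= self.window_start_fraction < 1.0:
            raise ConfigError("window_start_fraction: must be in [0, 1)")
        if not self.dt > 0:
            raise ConfigError("dt: must be > 0")
        if self.t_end < 0:
            raise ConfigError("t_end: must be >= 0")
        if self.engine == "continuous" and self.s > 0:
            raise ConfigError(
                "s: the continuous engine cannot represent sloughing (s > 0)"
            )

    # --- derived model objects -------------------------------------------
    @property
    def taxa(self) -> TaxonSet:
        return TaxonSet(self.labels)

    @property
    def initial_state(self) -> DiscreteState:
        return DiscreteState.from_composition(self.f, self.N)

    @property
    def selection(self) -> SelectionParams:
        return SelectionParams(np.asarray(self.alpha), np.asarray(self.beta))

    @property
    def migration(self) -> MigrationParams:
        return MigrationParams(m=self.m, p=np.asarray(self.p), s=self.s,
                               N_s=self.N_s, p_die=self.p_die)

    @property
    def continuous_params(self) -> ContinuousParams:
        sel = self.selection
        return ContinuousParams(
            m_star=self.m * self.N,
            alpha_star=self.N * sel.net,
            p=np.asarray(self.p),
        )

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)


def load_config(path) -> RunConfig:
    """Parse and validate a JSON configuration file."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        data = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config file is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a JSON object")
    return RunConfig.from_dict(data)
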