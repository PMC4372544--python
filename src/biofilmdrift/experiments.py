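"""Preset scenarios and the replicate-sweep driver.

All presets use the three-group community (carrying-capacity buffer, bulk
water taxon, biofilm taxon) with the standard study conditions

    f = (0.2, 0.8, 0),  p = (0, 0, 1),  m = 0.04,  N = 10^3,

and 50 replicates per sweep cell.  The discrete scenarios sweep a selection
weight over {0, 0.02, ..., 0.1}; the continuous analogues sweep the matched
scaled coefficient over {0, 20, ..., 100}:

* ``fig1`` / ``s1fig``   — advantage to the bulk water taxon;
* ``fig2`` / ``s2fig``   — equal advantage to bulk and disadvantage to biofilm;
* ``fig3`` / ``s3fig``   — disadvantage to the biofilm taxon;
* ``fig4_sloughing``     — neutral, with sloughing (s = 1e-6, N_s = 1000,
  p_die = 0.5) over a shorter horizon;
* ``neutral_baseline``   — neutral, no sloughing.

Default horizons: 3e5 events (t = 0.3 diffusion units at N = 10^3) for the
steady-state scenarios, 5e4 events for the sloughing preset; overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .analysis import steady_state_summary, summaries_to_frame
from .continuous_sim import SDEConfig, simulate_continuous
from .core import (
    DEFAULT_TAXA,
    ConfigError,
    ContinuousParams,
    DiscreteState,
    MigrationParams,
    SelectionParams,
    Trajectory,
)
from .discrete_sim import simulate_discrete

__all__ = ["ScenarioPreset", "build_preset", "run_sweep", "PRESET_NAMES", "cell_seed"]

F0 = (0.2, 0.8, 0.0)
P0 = (0.0, 0.0, 1.0)
M0 = 0.04
N0 = 1000
N_RUNS = 50
DISCRETE_GRID = (0.0, 0.02, 0.04, 0.06, 0.08, 0.1)
CONTINUOUS_GRID = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
HORIZON_EVENTS = 300_000
HORIZON_SLOUGH = 50_000
T_END = HORIZON_EVENTS / N0**2  # matched continuous horizon
DT = 1e-5

#: taxon roles in the default 3-group community
BUFFER, BULK, BIOFILM = 0, 1, 2


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    engine: str  # "discrete" | "continuous"
    sweep_variable: str
    sweep_values: tuple
    n_runs: int = N_RUNS
    f: tuple = F0
    p: tuple = P0
    m: float = M0
    N: int = N0
    s: float = 0.0
    N_s: int = 0
    p_die: float = 0.0
    n_events: int = HORIZON_EVENTS
    t_end: float = T_END
    dt: float = DT
    record_every: int = 300  # events (discrete) or steps (continuous)

    def __post_init__(self) -> None:
        if self.engine not in ("discrete", "continuous"):
            raise ConfigError("engine must be 'discrete' or 'continuous'")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        if not np.all(np.isfinite(self.sweep_values)):
            raise ConfigError("sweep values must be finite")
        if self.engine == "continuous" and self.s > 0:
            raise ConfigError(
                "the continuous engine cannot represent sloughing (s > 0); "
                "use the discrete engine"
            )


def _sweep_selection(variable: str, value: float, r: int = 3) -> SelectionParams:
    """Selection vectors for one sweep cell of a discrete scenario."""
    alpha = np.zeros(r)
    beta = np.zeros(r)
    if variable == "alpha_bulk":
        alpha[BULK] = value
    elif variable == "alpha_bulk=beta_biofilm":
        alpha[BULK] = value
        beta[BIOFILM] = value
    elif variable == "beta_biofilm":
        beta[BIOFILM] = value
    elif variable == "none":
        pass
    else:
        raise ConfigError(f"unknown discrete sweep variable {variable!r}")
    return SelectionParams(alpha, beta)


def _sweep_alpha_star(variable: str, value: float, r: int = 3) -> np.ndarray:
    """alpha* vector for one sweep cell of a continuous scenario."""
    a = np.zeros(r)
    if variable == "alpha_star_bulk":
        a[BULK] = value
    elif variable == "alpha_star_bulk=-alpha_star_biofilm":
        a[BULK] = value
        a[BIOFILM] = -value
    elif variable == "alpha_star_biofilm_neg":
        a[BIOFILM] = -value
    elif variable == "none":
        pass
    else:
        raise ConfigError(f"unknown continuous sweep variable {variable!r}")
    return a


_REGISTRY: dict[str, ScenarioPreset] = {
    "fig1": ScenarioPreset("fig1", "discrete", "alpha_bulk", DISCRETE_GRID),
    "fig2": ScenarioPreset("fig2", "discrete", "alpha_bulk=beta_biofilm", DISCRETE_GRID),
    "fig3": ScenarioPreset("fig3", "discrete", "beta_biofilm", DISCRETE_GRID),
    "fig4_sloughing": ScenarioPreset(
        "fig4_sloughing", "discrete", "none", (0.0,),
        s=1e-6, N_s=1000, p_die=0.5, n_events=HORIZON_SLOUGH,
    ),
    "s1fig": ScenarioPreset("s1fig", "continuous", "alpha_star_bulk", CONTINUOUS_GRID),
    "s2fig": ScenarioPreset(
        "s2fig", "continuous", "alpha_star_bulk=-alpha_star_biofilm", CONTINUOUS_GRID
    ),
    "s3fig": ScenarioPreset(
        "s3fig", "continuous", "alpha_star_biofilm_neg", CONTINUOUS_GRID
    ),
    "neutral_baseline": ScenarioPreset("neutral_baseline", "discrete", "none", (0.0,)),
}

PRESET_NAMES = tuple(_REGISTRY)


def build_preset(name: str, **overrides) -> ScenarioPreset:
    """Look up a preset by name, optionally overriding fields (n_runs, ...)."""
    try:
        preset = _REGISTRY[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    return replace(preset, **overrides) if overrides else preset


def cell_seed(base_seed: int, sweep_index: int, run_index: int) -> int:
    """Deterministic, platform-independent seed for one (cell, replicate)."""
    ss = np.random.SeedSequence((int(base_seed), int(sweep_index), int(run_index)))
    return int(ss.generate_state(1)[0] % (2**31))


def _run_cell(preset: ScenarioPreset, value: float, seed: int) -> Trajectory:
    if preset.engine == "discrete":
        init = DiscreteState.from_composition(preset.f, preset.N)
        sel = _sweep_selection(preset.sweep_variable, value)
        mig = MigrationParams(m=preset.m, p=np.asarray(preset.p),
                              s=preset.s, N_s=preset.N_s, p_die=preset.p_die)
        return simulate_discrete(init, sel, mig, preset.n_events, seed,
                                 preset.record_every, taxa=DEFAULT_TAXA)
    params = ContinuousParams(
        m_star=preset.m * preset.N,
        alpha_star=_sweep_alpha_star(preset.sweep_variable, value),
        p=np.asarray(preset.p),
    )
    cfg = SDEConfig(dt=preset.dt, t_end=preset.t_end,
                    record_every=preset.record_every)
    return simulate_continuous(np.asarray(preset.f), params, cfg, seed,
                               taxa=DEFAULT_TAXA)


def run_sweep(
    preset: ScenarioPreset,
    seed: int,
    *,
    window_start_fraction: float = 0.5,
    keep_trajectories: bool = True,
):
    """Run ``n_runs`` replicates per sweep value.

    Returns ``(trajectories, summary)`` where ``trajectories`` maps
    ``(sweep_value, run_index)`` to a :class:`Trajectory` (empty dict when
    ``keep_trajectories=False``) and ``summary`` is a long DataFrame with one
    row per replicate per taxon, annotated with the sweep value.
    """
    import pandas as pd

    trajs: dict[tuple[float, int], Trajectory] = {}
    frames = []
    for si, value in enumerate(preset.sweep_values):
        summaries = []
        for run in range(preset.n_runs):
            t = _run_cell(preset, value, cell_seed(seed, si, run))
            if keep_trajectories:
                trajs[(value, run)] = t
            summaries.append(
                steady_state_summary(t, window_start_fraction, replicate=run)
            )
        frame = summaries_to_frame(summaries, DEFAULT_TAXA)
        frame.insert(0, preset.sweep_variable if preset.sweep_variable != "none"
                     else "sweep_value", value)
        frames.append(frame)
    return trajs, pd.concat(frames, ignore_index=True)
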