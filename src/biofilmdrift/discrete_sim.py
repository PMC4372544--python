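"""Event-driven simulator of the discrete birth/migration-death process.

Each event is a categorical draw with probabilities ``(1 - m - s, m, s)``:

* **local birth** — one individual dies (drawn with disadvantage-weighted
  probabilities d_i) and is replaced by the offspring of one drawn with
  advantage-weighted probabilities b_i;
* **migration** — the death is instead replaced by a migrant drawn from the
  source (biofilm) composition ``p``;
* **sloughing** — a biofilm aggregate detaches: ``N_s`` individuals enter at
  once, a fraction ``p_die`` of them dying instantly and being converted to
  carrying-capacity buffer, the survivors allocated multinomially from ``p``.

Both the death draw and the replacement draw use the state *before* the
death, i.e. the dying individual remains in the replacement pool; the
alternative convention differs only at O(1/N).  Null events (the same taxon
dies and is born) count as events, keeping the event-type probabilities
exactly ``(1 - m - s, m, s)``.  Total community size is conserved except
under sloughing, where each event adds exactly ``N_s``.

Time is measured in events; mapping events to real time requires
system-specific calibration and is deliberately left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import (
    DEFAULT_TAXA,
    DiscreteState,
    MigrationParams,
    ParameterError,
    SelectionParams,
    StateError,
    TaxonSet,
    Trajectory,
    _largest_remainder,
)

__all__ = [
    "EventRecord",
    "step",
    "sloughing_event",
    "simulate_discrete",
    "simulate_replicates",
    "time_to_boundary",
    "replicate_seed",
]

EVENT_TYPES = ("local_birth", "migration", "sloughing")


@dataclass(frozen=True)
class EventRecord:
    event_type: str  # "local_birth" | "migration" | "sloughing"
    died_taxon: int | None
    born_taxon: int | None
    event_index: int | None = None


def _weighted_index(rng: np.random.Generator, weights: np.ndarray) -> int:
    s = weights.sum()
    if not np.isfinite(s) or s <= 0:
        raise ParameterError("event weights are not a finite positive vector")
    return int(rng.choice(weights.size, p=weights / s))


def sloughing_event(
    state: DiscreteState,
    mig: MigrationParams,
    rng: np.random.Generator | None = None,
    *,
    buffer_index: int = 0,
    expected_alloc: bool = False,
) -> DiscreteState:
    """Apply one sloughing event and return the new state.

    ``round(N_s * p_die)`` capacity units are added to the buffer; the
    remaining survivors are allocated across taxa by a multinomial draw from
    ``p`` (or deterministically in proportion to ``p`` with
    ``expected_alloc=True``, for testing).  The total grows by exactly
    ``N_s``.
    """
    counts = state.counts.copy()
    n_die = int(round(mig.N_s * mig.p_die))
    survivors = mig.N_s - n_die
    counts[buffer_index] += n_die
    if survivors > 0:
        if expected_alloc:
            counts += _largest_remainder(survivors * mig.p, survivors)
        else:
            if rng is None:
                raise ParameterError("stochastic allocation requires an rng")
            counts += rng.multinomial(survivors, mig.p)
    return DiscreteState(counts)


def step(
    state: DiscreteState,
    sel: SelectionParams,
    mig: MigrationParams,
    rng: np.random.Generator,
    *,
    buffer_index: int = 0,
    expected_alloc: bool = False,
) -> tuple[DiscreteState, EventRecord]:
    """Advance the community by a single event.

    Returns the new state and a record of what happened.  For local-birth
    and migration events the total is unchanged (one count down, one up,
    possibly the same taxon); sloughing delegates to
    :func:`sloughing_event`.
    """
    if state.total < 1:
        raise StateError("community is empty")
    counts = state.counts
    u = rng.random()
    if u < 1.0 - mig.m - mig.s:
        ev = "local_birth"
    elif u < 1.0 - mig.s:
        ev = "migration"
    else:
        ev = "sloughing"

    if ev == "sloughing":
        new = sloughing_event(state, mig, rng, buffer_index=buffer_index,
                              expected_alloc=expected_alloc)
        return new, EventRecord("sloughing", None, None)

    died = _weighted_index(rng, (1.0 + sel.beta) * counts)
    if ev == "local_birth":
        born = _weighted_index(rng, (1.0 + sel.alpha) * counts)
    else:
        born = _weighted_index(rng, mig.p)
    new_counts = counts.copy()
    new_counts[died] -= 1
    new_counts[born] += 1
    return DiscreteState(new_counts), EventRecord(ev, died, born)


def _params_dict(sel: SelectionParams, mig: MigrationParams) -> dict:
    return {
        "alpha": sel.alpha.tolist(),
        "beta": sel.beta.tolist(),
        "m": mig.m,
        "p": mig.p.tolist(),
        "s": mig.s,
        "N_s": mig.N_s,
        "p_die": mig.p_die,
    }


def simulate_discrete(
    init: DiscreteState,
    sel: SelectionParams,
    mig: MigrationParams,
    n_events: int,
    seed: int,
    record_every: int = 1,
    *,
    taxa: TaxonSet | None = None,
    expected_alloc: bool = False,
) -> Trajectory:
    """Run one replicate for ``n_events`` events.

    The trajectory holds ``n_events // record_every + 1`` records, the first
    being the initial state at event 0.  Identical seeds give bitwise
    identical trajectories.
    """
    if n_events < 0:
        raise ParameterError("n_events must be >= 0")
    if record_every < 1:
        raise ParameterError("record_every must be >= 1")
    if taxa is None:
        taxa = DEFAULT_TAXA if init.counts.size == 3 else TaxonSet(
            tuple(f"taxon{i}" for i in range(init.counts.size)))
    if mig.p.size != init.counts.size:
        raise ParameterError("p and counts must have the same length")
    ev_idx, rec = _kernels.run_discrete(
        init.counts.astype(np.int64),
        sel.alpha.astype(np.float64),
        sel.beta.astype(np.float64),
        mig.p.astype(np.float64),
        float(mig.m), float(mig.s), np.int64(mig.N_s), float(mig.p_die),
        np.int64(taxa.buffer_index),
        np.int64(n_events), np.int64(record_every), np.int64(seed),
        expected_alloc,
    )
    return Trajectory(
        index=ev_idx,
        values=rec,
        kind="discrete",
        taxa=taxa,
        seed=int(seed),
        record_every=int(record_every),
        params=_params_dict(sel, mig),
    )


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Seed for replicate ``replicate`` of a batch started at ``base_seed``."""
    return int(base_seed) + int(replicate)


def simulate_replicates(
    init: DiscreteState,
    sel: SelectionParams,
    mig: MigrationParams,
    n_events: int,
    n_runs: int,
    base_seed: int,
    record_every: int = 1,
    **kwargs,
) -> list[Trajectory]:
    """``n_runs`` independent replicates with seeds base_seed + 0, 1, ..."""
    return [
        simulate_discrete(init, sel, mig, n_events,
                          replicate_seed(base_seed, i), record_every, **kwargs)
        for i in range(n_runs)
    ]


def time_to_boundary(
    init: DiscreteState,
    sel: SelectionParams,
    mig: MigrationParams,
    taxon: int,
    *,
    fixation: bool,
    max_events: int,
    seed: int,
    buffer_index: int = 0,
) -> int | None:
    """Event index at which ``taxon`` first hits count 0 (``fixation=False``)
    or occupies the whole community (``fixation=True``); None if this does
    not happen within ``max_events``."""
    e = _kernels.run_until_boundary(
        init.counts.astype(np.int64),
        sel.alpha.astype(np.float64),
        sel.beta.astype(np.float64),
        mig.p.astype(np.float64),
        float(mig.m), float(mig.s), np.int64(mig.N_s), float(mig.p_die),
        np.int64(buffer_index),
        np.int64(taxon), not fixation, np.int64(max_events), np.int64(seed),
        False,
    )
    return None if e < 0 else int(e)
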