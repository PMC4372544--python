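"""Domain types and probability kernels shared by both model formulations.

The community in a packet of fluid is described by ``r`` taxa, one of which
(by convention index 0) is the *carrying-capacity buffer*: a pseudo-taxon
whose abundance is the unfilled capacity of the packet.  The buffer behaves
exactly like any other taxon — its "death" fills capacity, its "birth" frees
capacity — which lets total live-cell numbers vary without breaking the
fixed-size bookkeeping of the underlying Moran-type process.

Selection enters through two non-negative weight vectors: an advantage
vector ``alpha`` up-weights a taxon's chance of being chosen to replicate,
a disadvantage vector ``beta`` up-weights its chance of being chosen to die,

    b_i = (1 + alpha_i) x_i / (1 + sum_j alpha_j x_j)
    d_i = (1 + beta_i)  x_i / (1 + sum_j beta_j  x_j)

where ``x`` is the current relative-abundance vector.  In the diffusion
limit (community size N -> infinity with m and alpha - beta of order 1/N)
only the products ``m* = m N`` and ``alpha* = N (alpha - beta)`` survive;
:func:`match_parameters` performs that scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "StateError",
    "ConfigError",
    "TaxonSet",
    "as_composition",
    "DiscreteState",
    "SelectionParams",
    "MigrationParams",
    "ContinuousParams",
    "Trajectory",
    "birth_probabilities",
    "death_probabilities",
    "match_parameters",
]

#: below this distance from the simplex a composition is renormalized silently;
#: above it the input is rejected.
SIMPLEX_TOL = 1e-9


class ParameterError(ValueError):
    """A model parameter violates its domain (negative weight, N < 1, ...)."""


class ConfigError(ValueError):
    """A configuration file, preset name or scenario definition is invalid."""


class StateError(ValueError):
    """A community state is invalid (off the simplex, empty community, ...)."""


@dataclass(frozen=True)
class TaxonSet:
    """Ordered taxon labels, including the carrying-capacity buffer.

    Parameters
    ----------
    labels
        Unique names for the ``r`` taxa.  ``r >= 2``.
    buffer_index
        Position of the carrying-capacity buffer taxon.  Defaults to 0,
        matching the convention that the buffer is listed first.
    """

    labels: tuple[str, ...]
    buffer_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 2:
            raise ParameterError("need at least two taxa (r >= 2)")
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("taxon labels must be unique")
        if not 0 <= self.buffer_index < len(self.labels):
            raise ParameterError("buffer_index out of range")

    @property
    def r(self) -> int:
        return len(self.labels)


DEFAULT_TAXA = TaxonSet(("buffer", "bulk", "biofilm"))


def as_composition(x: Sequence[float] | np.ndarray, *, name: str = "x") -> np.ndarray:
    """Validate ``x`` as a point on the probability simplex and return it.

    Entries must be in [0, 1] and sum to 1.  Deviations of the sum below
    ``SIMPLEX_TOL`` are renormalized silently; larger ones raise
    :class:`StateError`.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise StateError(f"{name} must be a 1-d vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise StateError(f"{name} has non-finite entries")
    if np.any(x < -SIMPLEX_TOL) or np.any(x > 1 + SIMPLEX_TOL):
        raise StateError(f"{name} has entries outside [0, 1]")
    s = x.sum()
    if abs(s - 1.0) > SIMPLEX_TOL:
        raise StateError(f"{name} sums to {s!r}, not 1")
    x = np.clip(x, 0.0, None)
    return x / x.sum()


def _check_weights(w: Sequence[float] | np.ndarray, name: str, r: int | None = None) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ParameterError(f"{name} has non-finite entries")
    if np.any(w < 0):
        raise ParameterError(f"{name} has negative entries")
    if r is not None and w.shape != (r,):
        raise ParameterError(f"{name} must have length {r}")
    return w


@dataclass(frozen=True)
class DiscreteState:
    """Integer counts per taxon; buffer 'individuals' are unfilled capacity units."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or c.size < 2:
            raise StateError("counts must be a 1-d vector of length >= 2")
        if np.any(c < 0):
            raise StateError("counts must be non-negative")
        if c.sum() < 1:
            raise StateError("community must contain at least one individual")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def composition(self) -> np.ndarray:
        return self.counts / self.total

    @classmethod
    def from_composition(cls, f: Sequence[float], N: int) -> "DiscreteState":
        """Build integer counts ``~ f * N`` (largest-remainder rounding)."""
        if N < 1:
            raise ParameterError("N must be >= 1")
        f = as_composition(f, name="f")
        return cls(_largest_remainder(f * N, N))


def _largest_remainder(target: np.ndarray, total: int) -> np.ndarray:
    """Round a non-negative vector to integers preserving its (integer) sum."""
    base = np.floor(target).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(target - base), kind="stable")
        base[order[:short]] += 1
    return base


@dataclass(frozen=True)
class SelectionParams:
    """Advantage (alpha) and disadvantage (beta) weight vectors, length r."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        a = _check_weights(self.alpha, "alpha")
        b = _check_weights(self.beta, "beta", r=a.size)
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)

    @classmethod
    def neutral(cls, r: int) -> "SelectionParams":
        return cls(np.zeros(r), np.zeros(r))

    @property
    def net(self) -> np.ndarray:
        """alpha - beta: the only combination that survives the diffusion limit."""
        return self.alpha - self.beta


@dataclass(frozen=True)
class MigrationParams:
    """Migration, sloughing and source-community parameters of the discrete model.

    m
        Probability that a death event is coupled to replacement by a migrant
        from the source (biofilm) community rather than a local birth.
    p
        Source-community composition the migrant (and sloughed cells) are
        drawn from.
    s
        Probability per event of a sloughing event: a biofilm aggregate
        detaches and injects ``N_s`` individuals at once.
    N_s
        Number of individuals introduced per sloughing event.
    p_die
        Fraction of sloughed individuals that die instantly (e.g. from
        disinfectant); they are converted to carrying-capacity buffer.
    """

    m: float
    p: np.ndarray
    s: float = 0.0
    N_s: int = 0
    p_die: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.m) and 0.0 <= self.m <= 1.0):
            raise ParameterError("m must be in [0, 1]")
        if not (np.isfinite(self.s) and 0.0 <= self.s <= 1.0):
            raise ParameterError("s must be in [0, 1]")
        if self.m + self.s > 1.0:
            raise ParameterError("m + s must not exceed 1")
        if self.N_s < 0:
            raise ParameterError("N_s must be >= 0")
        if not (np.isfinite(self.p_die) and 0.0 <= self.p_die <= 1.0):
            raise ParameterError("p_die must be in [0, 1]")
        object.__setattr__(self, "p", as_composition(self.p, name="p"))
        object.__setattr__(self, "N_s", int(self.N_s))


@dataclass(frozen=True)
class ContinuousParams:
    """Scaled parameters of the diffusion model.

    m_star
        Migration rate per diffusion time unit (= m N in the discrete model).
    alpha_star
        Net selection coefficients per diffusion time unit (= N (alpha - beta)).
    sigma
        Noise amplitude; 1 under the convention that one diffusion time unit
        corresponds to N^2 discrete events.
    p
        Source-community composition.
    """

    m_star: float
    alpha_star: np.ndarray
    p: np.ndarray
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.m_star) and self.m_star >= 0):
            raise ParameterError("m_star must be finite and >= 0")
        if not (np.isfinite(self.sigma) and self.sigma >= 0):
            raise ParameterError("sigma must be finite and >= 0")
        a = np.asarray(self.alpha_star, dtype=float)
        if not np.all(np.isfinite(a)):
            raise ParameterError("alpha_star has non-finite entries")
        object.__setattr__(self, "alpha_star", a)
        object.__setattr__(self, "p", as_composition(self.p, name="p"))
        if self.p.size != a.size:
            raise ParameterError("alpha_star and p must have the same length")


@dataclass
class Trajectory:
    """Recorded time series of one replicate.

    ``index`` holds event numbers (discrete engine) or times in diffusion
    units (continuous engine); ``values`` is the ``(k, r)`` array of counts
    or relative abundances at those indices.  The first record is always the
    initial state at index 0.
    """

    index: np.ndarray
    values: np.ndarray
    kind: str  # "discrete" | "continuous"
    taxa: TaxonSet
    seed: int
    record_every: int
    params: dict = field(default_factory=dict)
    boundary_eps: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous"):
            raise ParameterError("kind must be 'discrete' or 'continuous'")
        if len(self.index) != len(self.values):
            raise StateError("index and values length mismatch")
        if len(self.index) > 1 and not np.all(np.diff(self.index) > 0):
            raise StateError("trajectory indices must be strictly increasing")

    @property
    def n_records(self) -> int:
        return len(self.index)

    @property
    def r(self) -> int:
        return self.values.shape[1]

    @property
    def rel_abundance(self) -> np.ndarray:
        """(k, r) relative abundances; identity for the continuous engine."""
        if self.kind == "continuous":
            return self.values
        tot = self.values.sum(axis=1, keepdims=True)
        return self.values / tot

    def to_frame(self, run: int = 0):
        """Long-format DataFrame, one row per record per taxon."""
        import pandas as pd

        k, r = self.values.shape
        rel = self.rel_abundance
        out = {
            "run": np.repeat(run, k * r),
            ("event" if self.kind == "discrete" else "time"): np.repeat(self.index, r),
            "taxon": np.tile(np.asarray(self.taxa.labels), k),
        }
        if self.kind == "discrete":
            out["count"] = self.values.ravel()
        out["rel_abundance"] = rel.ravel()
        return pd.DataFrame(out)


def birth_probabilities(x: Sequence[float] | np.ndarray, alpha: Sequence[float] | np.ndarray) -> np.ndarray:
    """Birth (replication) probabilities b_i = (1+alpha_i) x_i / (1 + alpha.x).

    Reduces to ``x`` itself when ``alpha`` is zero (the neutral case) and
    assigns zero probability to absent taxa regardless of their advantage.
    """
    x = as_composition(x)
    alpha = _check_weights(alpha, "alpha", r=x.size)
    if not alpha.any():  # neutral: identity, exactly
        return x
    w = (1.0 + alpha) * x
    return w / w.sum()


def death_probabilities(x: Sequence[float] | np.ndarray, beta: Sequence[float] | np.ndarray) -> np.ndarray:
    """Death probabilities d_i = (1+beta_i) x_i / (1 + beta.x)."""
    x = as_composition(x)
    beta = _check_weights(beta, "beta", r=x.size)
    if not beta.any():  # neutral: identity, exactly
        return x
    w = (1.0 + beta) * x
    return w / w.sum()


def match_parameters(
    m: float,
    alpha: Sequence[float] | np.ndarray,
    beta: Sequence[float] | np.ndarray,
    N: int,
    p: Sequence[float] | np.ndarray | None = None,
) -> ContinuousParams:
    """Scale discrete parameters to their diffusion-limit equivalents.

    ``m* = m N`` and ``alpha* = N (alpha - beta)``; ``sigma = 1`` under the
    convention that one diffusion time unit equals N^2 discrete events.
    For fixed N the map is a bijection between (m, alpha - beta) and
    (m*, alpha*).

    Parameters
    ----------
    p
        Optional source composition to carry along; defaults to uniform-free
        placeholder being *required* downstream, so pass it when you intend
        to simulate.
    """
    if N < 1:
        raise ParameterError("N must be >= 1")
    alpha = _check_weights(alpha, "alpha")
    beta = _check_weights(beta, "beta", r=alpha.size)
    if p is None:
        # default: pure-source at the last taxon is NOT assumed; use uniform
        p_arr = np.full(alpha.size, 1.0 / alpha.size)
    else:
        p_arr = as_composition(p, name="p")
    return ContinuousParams(
        m_star=m * N,
        alpha_star=N * (alpha - beta),
        p=p_arr,
        sigma=1.0,
    )
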