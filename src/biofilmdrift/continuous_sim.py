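"""Euler-Maruyama integrator for the diffusion limit on the simplex.

The diffusion is  dX = M dt + sigma sqrt(V) dW  with drift

    M_i = m* (p_i - X_i) + alpha*_i X_i - (alpha* . X) X_i

and Wright-Fisher covariance V_ii = 2 X_i (1 - X_i), V_ij = -2 X_i X_j.
Since abundances sum to one, V is singular of rank r - 1; rather than
factorize a reduced matrix numerically we use the exact square root

    dB_i = sigma sqrt(2 dt) * ( sqrt(X_i) z_i - X_i * sum_k sqrt(X_k) z_k )

with iid standard normals z, whose covariance is exactly sigma^2 V dt and
whose components sum to zero identically, so each step stays on the
hyperplane by construction.  Negative excursions are clipped to zero and the
state renormalized; a coordinate clipped to zero whose source entry p_i = 0
is frozen there, mirroring the absorbing behaviour of the discrete process.

Sloughing (an instantaneous influx of many individuals) has no natural
diffusion analogue, so configurations with s > 0 must use the discrete
engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import (
    DEFAULT_TAXA,
    ContinuousParams,
    ParameterError,
    TaxonSet,
    Trajectory,
    as_composition,
)

__all__ = ["SDEConfig", "drift", "variance_matrix", "sde_step", "simulate_continuous"]


@dataclass(frozen=True)
class SDEConfig:
    """Integration settings.

    dt
        Time step in diffusion units.  The default 1e-5 corresponds, at
        N = 10^3, to about ten discrete events per step.
    t_end
        Horizon in diffusion units (1 unit ~ N^2 events).
    boundary_eps
        Abundances at or below this are treated as zero.
    record_every
        Recording stride in steps.
    """

    dt: float = 1e-5
    t_end: float = 1.0
    boundary_eps: float = 1e-8
    record_every: int = 100

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ParameterError("dt must be > 0")
        if self.t_end < 0:
            raise ParameterError("t_end must be >= 0")
        if not (0 <= self.boundary_eps < 1e-3):
            raise ParameterError("boundary_eps must be in [0, 1e-3)")
        if self.record_every < 1:
            raise ParameterError("record_every must be >= 1")


def drift(x: np.ndarray, params: ContinuousParams) -> np.ndarray:
    """Drift vector M(x); components sum to zero (tangent to the simplex)."""
    x = as_composition(x)
    a = params.alpha_star
    if a.size != x.size:
        raise ParameterError("alpha_star and x must have the same length")
    ax = float(a @ x)
    return params.m_star * (params.p - x) + a * x - ax * x


def variance_matrix(x: np.ndarray) -> np.ndarray:
    """Wright-Fisher covariance V = 2 (diag(x) - x x^T).

    Symmetric, positive semidefinite, rows sum to zero; rank r - 1 for
    interior x and identically zero at a vertex.
    """
    x = as_composition(x)
    return 2.0 * (np.diag(x) - np.outer(x, x))


def sde_step(
    x: np.ndarray,
    params: ContinuousParams,
    cfg: SDEConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Euler-Maruyama step; returns a simplex vector.

    With sigma = 0 this is a deterministic Euler step.  Coordinates at zero
    with zero source abundance stay at zero (both drift and noise vanish
    there and clipping freezes any round-off).
    """
    x = as_composition(x)
    m = drift(x, params)
    z = rng.standard_normal(x.size)
    sx = np.sqrt(x)
    noise = params.sigma * np.sqrt(2.0 * cfg.dt) * (sx * z - x * (sx @ z))
    y = x + m * cfg.dt + noise
    y[y <= cfg.boundary_eps] = 0.0
    y[(x == 0.0) & (params.p == 0.0)] = 0.0
    return y / y.sum()


def simulate_continuous(
    f: np.ndarray,
    params: ContinuousParams,
    cfg: SDEConfig,
    seed: int,
    *,
    taxa: TaxonSet | None = None,
) -> Trajectory:
    """Integrate one path from composition ``f`` to ``cfg.t_end``.

    The trajectory records every ``cfg.record_every``-th step, starting with
    the initial state at time 0.  Identical seeds give identical paths.
    """
    f = as_composition(f, name="f")
    if params.p.size != f.size:
        raise ParameterError("p and f must have the same length")
    if taxa is None:
        taxa = DEFAULT_TAXA if f.size == 3 else TaxonSet(
            tuple(f"taxon{i}" for i in range(f.size)))
    n_steps = int(round(cfg.t_end / cfg.dt))
    times, rec = _kernels.run_sde(
        f.astype(np.float64),
        params.p.astype(np.float64),
        float(params.m_star),
        params.alpha_star.astype(np.float64),
        float(params.sigma),
        float(cfg.dt),
        np.int64(n_steps),
        np.int64(cfg.record_every),
        float(cfg.boundary_eps),
        np.int64(seed),
    )
    return Trajectory(
        index=times,
        values=rec,
        kind="continuous",
        taxa=taxa,
        seed=int(seed),
        record_every=int(cfg.record_every),
        params={
            "m_star": params.m_star,
            "alpha_star": params.alpha_star.tolist(),
            "sigma": params.sigma,
            "p": params.p.tolist(),
            "dt": cfg.dt,
            "t_end": cfg.t_end,
        },
        boundary_eps=cfg.boundary_eps,
    )
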