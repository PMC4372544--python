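"""Numba-jitted inner loops for the discrete event process and the SDE.

Each jitted entry point seeds numba's internal legacy RNG, so a given
(seed, parameters) pair is bitwise reproducible.  The pure-Python single-step
functions in :mod:`biofilmdrift.discrete_sim` / :mod:`.continuous_sim`
implement the same sampling rules on a numpy ``Generator``; the batch
kernels here exist purely for throughput and do not share their stream.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# event-type codes
LOCAL_BIRTH = 0
MIGRATION = 1
SLOUGHING = 2


@njit(cache=True)
def _weighted_draw(weights, wsum):
    """Index ~ Categorical(weights / wsum)."""
    u = np.random.random() * wsum
    acc = 0.0
    last = -1
    for i in range(weights.shape[0]):
        if weights[i] <= 0.0:
            continue
        last = i
        acc += weights[i]
        if u < acc:
            return i
    return last


@njit(cache=True)
def _expected_value_alloc(counts, p, survivors):
    """Deterministic largest-remainder allocation of survivors ~ survivors*p."""
    r = p.shape[0]
    exact = np.empty(r)
    base = np.empty(r, dtype=np.int64)
    for i in range(r):
        exact[i] = survivors * p[i]
        base[i] = np.int64(math.floor(exact[i]))
    short = survivors - base.sum()
    if short > 0:
        frac = base.astype(np.float64) - exact  # most negative = largest remainder
        order = np.argsort(frac)
        for j in range(short):
            base[order[j]] += 1
    for i in range(r):
        counts[i] += base[i]


@njit(cache=True)
def _multinomial_alloc(counts, p, survivors):
    """Stochastic multinomial allocation via a binomial chain."""
    remaining = survivors
    psum = 1.0
    r = p.shape[0]
    for i in range(r):
        if remaining <= 0:
            break
        if psum <= 1e-15:
            counts[i] += remaining
            remaining = 0
            break
        pi = p[i] / psum
        if pi >= 1.0 or i == r - 1:
            k = remaining
        else:
            k = np.random.binomial(remaining, pi)
        counts[i] += k
        remaining -= k
        psum -= p[i]


@njit(cache=True)
def _one_event(counts, total, alpha, beta, p, m, s, N_s, p_die, buffer_index, expected_alloc):
    """Advance the community by one event in place; return the new total."""
    u = np.random.random()
    if u < 1.0 - m - s:
        ev = LOCAL_BIRTH
    elif u < 1.0 - s:
        ev = MIGRATION
    else:
        ev = SLOUGHING
    r = counts.shape[0]

    if ev == SLOUGHING:
        n_die = np.int64(round(N_s * p_die))
        counts[buffer_index] += n_die
        survivors = N_s - n_die
        if survivors > 0:
            if expected_alloc:
                _expected_value_alloc(counts, p, survivors)
            else:
                _multinomial_alloc(counts, p, survivors)
        return total + N_s

    # death draw, weights (1 + beta_i) * counts_i  (Eq. 2 on counts)
    w = np.empty(r)
    wsum = 0.0
    for i in range(r):
        w[i] = (1.0 + beta[i]) * counts[i]
        wsum += w[i]
    died = _weighted_draw(w, wsum)

    if ev == LOCAL_BIRTH:
        # birth weights from the pre-death state: the dying individual
        # remains in the replacement pool
        bsum = 0.0
        for i in range(r):
            w[i] = (1.0 + alpha[i]) * counts[i]
            bsum += w[i]
        born = _weighted_draw(w, bsum)
    else:
        born = _weighted_draw(p, 1.0)

    counts[died] -= 1
    counts[born] += 1
    return total


@njit(cache=True)
def run_discrete(counts0, alpha, beta, p, m, s, N_s, p_die, buffer_index,
                 n_events, record_every, seed, expected_alloc):
    """Simulate n_events and record every record_every-th state.

    Returns (event_index array, counts array of shape (k, r)); the first
    record is the initial state at event 0.
    """
    np.random.seed(seed)
    counts = counts0.copy()
    total = np.int64(counts.sum())
    r = counts.shape[0]
    n_rec = n_events // record_every + 1
    rec = np.zeros((n_rec, r), dtype=np.int64)
    ev_idx = np.zeros(n_rec, dtype=np.int64)
    rec[0] = counts
    k = 1
    for e in range(1, n_events + 1):
        total = _one_event(counts, total, alpha, beta, p, m, s, N_s, p_die,
                           buffer_index, expected_alloc)
        if e % record_every == 0:
            rec[k] = counts
            ev_idx[k] = e
            k += 1
    return ev_idx[:k], rec[:k]


@njit(cache=True)
def run_until_boundary(counts0, alpha, beta, p, m, s, N_s, p_die, buffer_index,
                       target, hit_zero, max_events, seed, expected_alloc):
    """Event index at which counts[target] first hits 0 (hit_zero) or the
    whole community (fixation); -1 if neither happens within max_events."""
    np.random.seed(seed)
    counts = counts0.copy()
    total = np.int64(counts.sum())
    if hit_zero and counts[target] == 0:
        return np.int64(0)
    if (not hit_zero) and counts[target] == total:
        return np.int64(0)
    for e in range(1, max_events + 1):
        total = _one_event(counts, total, alpha, beta, p, m, s, N_s, p_die,
                           buffer_index, expected_alloc)
        if hit_zero:
            if counts[target] == 0:
                return np.int64(e)
        elif counts[target] == total:
            return np.int64(e)
    return np.int64(-1)


@njit(cache=True)
def run_sde(x0, p, m_star, alpha_star, sigma, dt, n_steps, record_every,
            boundary_eps, seed):
    """Euler-Maruyama path of the Wright-Fisher-with-migration diffusion.

    The noise increment uses the exact square root of the covariance
    V = 2 (diag(x) - x x^T):  dB_i = sqrt(2 dt) (sqrt(x_i) z_i - x_i S),
    S = sum_k sqrt(x_k) z_k, with iid standard normal z.  Coordinates
    clipped to zero whose source entry p_i = 0 are frozen there (the
    discrete process can never revive them either).
    """
    np.random.seed(seed)
    r = x0.shape[0]
    x = x0.copy()
    frozen = np.zeros(r, dtype=np.bool_)
    for i in range(r):
        if x[i] <= boundary_eps and p[i] == 0.0:
            x[i] = 0.0
            frozen[i] = True
    tot = x.sum()
    for i in range(r):
        x[i] /= tot

    n_rec = n_steps // record_every + 1
    rec = np.zeros((n_rec, r))
    times = np.zeros(n_rec)
    rec[0] = x
    k = 1
    sq2dt = sigma * math.sqrt(2.0 * dt)
    z = np.empty(r)
    sx = np.empty(r)
    for step in range(1, n_steps + 1):
        ax = 0.0
        for i in range(r):
            ax += alpha_star[i] * x[i]
        S = 0.0
        for i in range(r):
            z[i] = np.random.normal()
            sx[i] = math.sqrt(x[i])
            S += sx[i] * z[i]
        tot = 0.0
        for i in range(r):
            if frozen[i]:
                x[i] = 0.0
                continue
            drift = m_star * (p[i] - x[i]) + alpha_star[i] * x[i] - ax * x[i]
            noise = sq2dt * (sx[i] * z[i] - x[i] * S)
            xi = x[i] + drift * dt + noise
            if xi <= boundary_eps:
                xi = 0.0
                if p[i] == 0.0:
                    frozen[i] = True
            x[i] = xi
            tot += xi
        for i in range(r):
            x[i] /= tot
        if step % record_every == 0:
            rec[k] = x
            times[k] = step * dt
            k += 1
    return times[:k], rec[:k]
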