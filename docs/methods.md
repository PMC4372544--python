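# Methods

## Process definitions

### Discrete engine

The community is a vector of integer counts over `r` taxa; taxon 0 is by
convention the carrying-capacity buffer, which participates in every draw
exactly like a biological taxon.  One *event* is a categorical draw with
probabilities `(1 − m − s, m, s)`:

* **local birth** — an individual dies, chosen with probabilities
  `d_i ∝ (1 + β_i) x_i`, and is replaced by the offspring of an individual
  chosen with probabilities `b_i ∝ (1 + α_i) x_i`;
* **migration** — the death is replaced by a migrant drawn from the source
  composition `p`;
* **sloughing** — no death; `N_s` individuals enter at once.
  `round(N_s · p_die)` of them die instantly and are added to the buffer
  (dead biomass raises the carrying capacity); the
  `N_s − round(N_s · p_die)` survivors are allocated by a single multinomial
  draw from `p`.  A deterministic largest-remainder allocation in proportion
  to `p` is available behind a flag for exact bookkeeping tests.

Conventions worth stating because the process description leaves them open:

* Both the death draw and the replacement draw are computed from the state
  *before* the death — the dying individual remains in the replacement
  pool.  The alternative (excluding it) differs at O(1/N) and does not
  change any qualitative behaviour; we chose the variant in which death and
  replacement are a single instantaneous coupled event.
* Null events (the same taxon dies and is born) count as events, so the
  event-type probabilities are exactly `(1 − m − s, m, s)` rather than
  conditional on a visible change.
* There is no hard cap on community size under sloughing: capacity growth
  is represented by the buffer addition itself.
* Time is measured in events.  Mapping events to real time is
  system-specific (it depends on the per-capita death rate and the
  population size) and is deliberately not part of the model.

### Continuous engine

The diffusion limit on the simplex (valid for large `N` with `m` and
`α − β` of order `1/N`):

    dX = M dt + σ √V dW
    M_i  = m* (p_i − X_i) + α*_i X_i − (α*·X) X_i
    V_ii = 2 X_i (1 − X_i),   V_ij = −2 X_i X_j

with `m* = m N`, `α* = N(α − β)`, and `σ = 1` under the convention that one
diffusion time unit corresponds to `N²` events.  Only the net selection
`α − β` survives the limit, which is why the continuous parameter set
carries a single `alpha_star` vector while the discrete engine keeps `α`
and `β` separate.

Integration is Euler–Maruyama.  `V` is singular (rank `r − 1`, null vector
**1**), so instead of factorizing a reduced covariance matrix we sample the
noise increment through the exact analytic square root

    dB_i = σ √(2 dt) ( √X_i z_i − X_i Σ_k √X_k z_k ),   z_k iid N(0,1),

whose covariance is exactly `σ² V dt` and whose components sum to zero
identically — each step stays on the hyperplane by construction, costs
O(r), and has no factorization failure mode.

Boundary handling: after each step, coordinates at or below `boundary_eps`
are set to zero and the state renormalized; a coordinate clipped to zero
whose source entry `p_i = 0` is frozen at zero thereafter.  This mirrors
the discrete process, where a taxon with zero count and no immigration can
never return.  Sloughing has no natural diffusion analogue (it is a
macroscopic jump); configurations with `s > 0` are rejected by the
continuous engine.

## Parameters and defaults

| parameter | meaning | default | notes |
|---|---|---|---|
| `f` | initial packet composition | (0.2, 0.8, 0) | buffer, bulk, biofilm |
| `p` | source (biofilm) composition | (0, 0, 1) | no shared membership initially |
| `m` | migration probability per event | 0.04 | prior estimate for such systems |
| `N` | initial community size | 10³ | discrete engine only |
| `α, β` | selection weights | 0 | swept over 0…0.1 in steps of 0.02 |
| `α*` | net scaled selection | 0 | matched grid 0…±100 |
| `s` | sloughing probability per event | 10⁻⁶ | sloughing preset |
| `N_s` | individuals per sloughing event | 10³ | |
| `p_die` | instant-death fraction of sloughed cells | 0.5 | converted to buffer |
| `dt` | SDE step | 10⁻⁵ | ≈ 10 events-equivalent at N = 10³ |
| `boundary_eps` | zero threshold | 10⁻⁸ | |
| horizon | events / diffusion time | 3×10⁵ / 0.3 | 5×10⁴ for the sloughing preset |
| replicates | runs per condition | 50 | |

Scenario presets (`fig1`–`fig3`, `fig4_sloughing`, `s1fig`–`s3fig`,
`neutral_baseline`) bundle these into the standard designs: advantage to
the bulk taxon, equal-and-opposite advantage/disadvantage, disadvantage to
the biofilm taxon, and the sloughing run.  Exact per-panel horizons are not
part of the scenario definitions; 3×10⁵ events comfortably contains the
neutral fixation time scale (~10⁵ events) and is overridable.

## Analysis layer

* **Steady-window summaries**: per-taxon mean and *population* variance of
  relative abundance over the trailing window of records, default
  window start = 50 % of records.  "Seemingly steady" has no sharp
  definition, so the window start is a reported configuration knob.
* **Elimination time**: first *recorded* index at which a taxon's count
  (discrete) or abundance ≤ `boundary_eps` (continuous) is zero; with
  `record_every > 1` this overstates the true first passage by at most
  `record_every` events.  A taxon absent at the start reports index 0.
* **Extinction proportion**: fraction of replicates with a non-null
  elimination time.
* **Two-taxon absorption time.**  For one resident taxon and one migrant
  with source abundance 1, the expected time `T(b)` to full occupancy from
  migrant abundance `b` solves

      x(1−x) T'' + [ m*(1−x) + a* x(1−x) ] T' = −1,  T(1) = 0,

  with a reflecting condition at 0 (migration makes 0 inaccessible as long
  as `m* > 0`).  Integrating twice reduces this to the standard
  mean-first-passage quadrature with scale density `y^{−m*} e^{−a* y}`.  We
  evaluate the nested integrals on a grid uniform in `w = −log(1−y)` —
  the substitution cancels the `1/(1−z)` factor of the inner integrand
  analytically (no cancellation error near the boundary) and turns the
  logarithmic endpoint singularity of the outer integrand into a smooth,
  exponentially damped one.  The inner integral's head over `[0, b]` uses
  adaptive quadrature to resolve `z^{m*−1}` near zero.  Defaults: 4000
  panels, 16-point Gauss–Legendre per panel, cut-off `w_max = 40`
  (truncation error O(e⁻⁴⁰) relative).  Doubling the grid changes the
  result by well under 0.1 %; the neutral value agrees with 200 discrete
  Monte-Carlo fixation times within one standard error.

## Randomness and reproducibility

Batch simulations run in numba-compiled kernels seeded per replicate;
identical seeds give bitwise-identical trajectories and output files (no
timestamps are written).  Replicates of one batch use seeds
`base_seed + replicate`; sweep cells derive independent streams via
`SeedSequence((base_seed, sweep_index, run_index))`.  The pure-Python
single-step functions (`step`, `sde_step`) implement the same sampling
rules on a caller-supplied `numpy.random.Generator`; they share the rules,
not the stream, with the batch kernels.

## What the simulations do and do not show

All shipped scenarios use three lumped groups (buffer, bulk, biofilm) with
a homogeneous, time-constant source community and no shared membership
between bulk and biofilm at the start.  Real systems have many interacting
taxa, spatially heterogeneous biofilms, time-varying disinfectant levels
and flow-dependent sloughing; passing tests show the *process logic* and
the discrete↔continuous correspondence are right, not that any particular
pipe network behaves this way.  Extensions the interfaces leave room for
but the package does not implement: distributions over `p` (heterogeneous
source), taxon-specific migration weights (handled by reweighting `p` into
an "effective" source community upstream of the model), biofilm-side
dynamics, and hydraulically coupled sloughing magnitudes.

Known numerical limitations: the Euler–Maruyama scheme resolves the
absorbing boundary only to O(dt) — a dying taxon lingers at abundances of
order `dt` slightly longer than its discrete counterpart at matched
parameters; at `dt = 10⁻⁵` this bias is far below Monte-Carlo error in all
shipped comparisons.  The absorption-time quadrature is accurate for
`m* ≥ 1` and `|a*| ≤` a few hundred; far outside that range intermediate
factors can overflow and the solver raises rather than returning a wrong
number.
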