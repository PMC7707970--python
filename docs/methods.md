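# Methods

## Model

The package analyses the two-variable FitzHugh–Nagumo (FN) neuron

    du/dt = c (e u − u³/3 − v) + ξ(t)
    dv/dt = c (a u − b v)

with positive kinetic constants `a, b, c`, excitability `e`, membrane
potential `u`, linear recovery variable `v`, and a stochastic driver `ξ`
acting on the membrane-potential equation only. All quantities are
dimensionless. The reference parameter set used throughout the examples and
tests is `a = 2, b = 1.5, c = 1` with `e = 1` (monostable) or `e = 2`
(bistable).

Equilibria are obtained in closed form: the cubic nullcline intersection
factorises as `u₀ (u₀² − 3(e − a/b)) = 0` with `v₀ = a u₀ / b`, so a
supercritical pitchfork at `e = a/b` separates one equilibrium (the origin)
from three (`u₀ = ±√(3(e − a/b))` plus the origin). Stability follows the
Routh–Hurwitz conditions on the characteristic polynomial
`λ² + c₁ λ + c₀`, `c₁ = cb − ce + cu₀²`, `c₀ = cb(cu₀² − ce) + ac²`:
asymptotically stable iff both coefficients are positive, equivalently
`u₀² > max(e − b, (be − a)/b)`. A coefficient that is exactly zero is a
marginal case; it is reported as unstable with a `marginal` flag since the
linear test is inconclusive there.

## Noise

`ξ` is an α-stable process in the standard 1-parameterization
(α ∈ (0, 2], skewness β, scale γ, location δ); α = 2 is the Gaussian case
used in all headline experiments. Sampling uses the exact
Chambers–Mallows–Stuck transform; increments over a step `dt` carry the
self-similar scaling `γ·dt^(1/α)` (location `δ·dt`), which is the correct
Euler–Maruyama scaling for stable drivers. For α = 1 with β ≠ 0 we adopt
the standard sign convention for the logarithmic term (the sampler and the
characteristic function agree by construction); all experiments use β = 0,
where the conventions coincide.

Two diffusion conventions exist for α = 2: the noise-strength label
`d = γ^α` used to index sweeps, and the variance rate of the simulated
process, `D_u = 2γ²` (the α = 2 stable law with scale γ has variance 2γ²).
All Fokker–Planck solvers use the simulation-consistent `D_u`; `d` is
reported alongside as the sweep label.

## Simulation

Euler–Maruyama with defaults `dt = 0.01`, `t_end = 200` (the deterministic
relaxation time is O(1/c) = O(1), so it is well resolved; the order-1
convergence of the scheme is verified in the tests). Each node/path draws
from its own substream spawned from the master seed, so results are
reproducible and independent of how many units are simulated together; the
single-unit integrator is bit-for-bit the N = 1 zero-coupling network case.
Paths exceeding |u| = 10⁶ are truncated and flagged `diverged`.

Networks are K-nearest-neighbour rings (N nodes, K even): average local
clustering `cc = 3(K−2)/(4(K−1))` for K ≥ 4 and 0 for K = 2, so
K ∈ {2, 14, 20, 36} at N = 100 realises cc ∈ {0, 0.6923, 0.7105, 0.7286}.
Coupling is diffusive through the Laplacian `L = A − diag(deg)`:
`d₁ Σⱼ L_ij u_j` on u and `d₂ Σⱼ L_ij v_j` on v, vanishing on uniform
states. Defaults `d₁ = d₂ = 0.1`: weak relative to the local dynamics
(|L u| ≲ K·|Δu|, so per-neighbour pull 0.1 against O(1) local rates), yet
strong enough that network structure matters at K = 2.

Basin switches are scored with two-threshold hysteresis, defaults
`u_high = +1`, `u_low = −1` (≈ 70 % of the well position |u₀| = √2 in the
reference bistable setting): a unit in the low state must exceed `u_high`
to register a switch and then drop below `u_low` to switch back. This
suppresses chatter near the separatrix; dwell (retention) times are the
gaps between consecutive switches.

## First-passage times

The MFPT from a start point to an absorbing threshold is computed two ways:

1. **Monte Carlo** — independent Euler–Maruyama paths; the estimate is the
   mean first hitting time with censored paths (no exit by the horizon
   `t_max`) contributing `t_max` as a lower bound, counted and reported.
   Discrete threshold monitoring biases exit times upward by O(√dt); at the
   default `dt = 0.01` this is a few percent for the reference problems (the
   1-D double-well oracle test uses `dt = 0.002` where the bias is below the
   Monte-Carlo resolution).

2. **Backward Fokker–Planck** — the survival probability `G(x, t)` solves
   `∂ₜG = F·∇G + ½ D_u ∂_uu G + ½ ε ∂_vv G` with `G = 1` initially inside
   the rectangle, `G = 0` on the absorbing u-edge, reflecting (Neumann)
   conditions elsewhere, and `T(x) = ∫₀^∞ G dt`. Because noise enters u
   only, the operator is degenerate in v; a regularization `ε = 10⁻³·D_u`
   keeps the discrete problem elliptic. Advection uses a hybrid
   central/upwind finite-difference scheme (central where the cell Péclet
   number ≤ 2) so the system matrix is an M-matrix and the discrete maximum
   principle 0 ≤ G ≤ 1 holds; time stepping is implicit Euler (a short
   small-step phase for the fast transient, then large steps — the terminal
   decay is a single slow exponential, for which implicit Euler's rate error
   is (λ·dt)/2 ≪ 1). The time integral uses trapezoid quadrature on the
   recorded frames plus an exponential tail from the terminal decay rate;
   if `G` has not decayed below tolerance the field is flagged (or raises,
   if extrapolation is disabled). Default grid 141×141 on a rectangle with
   ≳ 20 % margin around the attractors; refining the grid moves the
   benchmark MFPT by < 5 %, and the PDE and Monte-Carlo estimates agree to
   ~1–2 % on the reference problem (e = 2, γ = 0.3).

Monte Carlo is the primary estimator (it covers α < 2 and any absorbing
rule); the PDE route is the independent cross-check.

## Network MFPT (NMFPT)

Per realization and node, τ is the first exit of a node from its *initial*
basin: `τ = inf{t : u_i(t) ≥ u_high}` for nodes starting low and
`τ = inf{t : u_i(t) ≤ u_low}` for nodes starting high. (Taking the
unrestricted minimum of the two threshold times would give τ = 0 at t = 0,
since a node resting at u₀ = −√2 already lies below `u_low`.) The pooled
NMFPT is the mean of τ over nodes and realizations with censored
node-realizations contributing the horizon — the same lower-bound
convention as the Monte-Carlo MFPT, and the only convention under which the
statistic estimates (a lower bound on) E[τ]. Initial conditions default to
`random_basin`: each node placed at the low/high stable equilibrium
independently with probability ½, freshly drawn per realization.

A crossing-conditioned mean (`nmfpt_observed`) is reported alongside: the
average of τ over node-realizations that exited within the horizon. It is
biased low under heavy censoring, but it is the quantity a finite
observation window naturally produces, and it behaves qualitatively
differently from the pooled mean: on the cc = 0 ring it *rises* with noise
at small γ (slow bulk exits begin to enter the window, joining the fast
exits of frustrated nodes whose neighbours disagree with them) before
falling at large γ. The pooled (horizon-bound) mean cannot show such a
rise at cc = 0: for γ → 0 no node leaves its basin — at γ = 0 no node of a
K = 2 ring crosses the separatrix at all under the default coupling, and
the per-node Kramers time ~exp(0.67/2γ²) exceeds any feasible horizon — so
the pooled statistic is pinned at the horizon for small γ and decreases
monotonically in γ. Both columns appear in every NMFPT table so either
reading is available. Sweep cells share one master seed (common random
numbers), making rows and columns of the (cc, γ) surface directly
comparable. Default horizon `t_end = 100` — several times the largest
finite single-unit MFPT within the swept γ range at moderate noise — with
`n_reps = 50` realizations of an N = 100 ring per cell.

## Stationary densities

The long-run joint density of (u, v) is estimated two ways: a normalized
2-D histogram of post-burn-in samples (default burn-in 20 % of each
trajectory — relaxation is O(1/c) — on a 121×121 grid over [−3, 3]², which
covers the attractors at |u| = √2 with margin), and the stationary solution
of the forward Fokker–Planck equation
`∂ₜP = −∇·(F P) + ½ D_u ∂_uu P + ½ ε ∂_vv P` in conservative finite-volume
form with zero-flux boundaries. Face fluxes use Scharfetter–Gummel
exponential fitting (positivity-preserving, exact for locally constant
coefficients, minimal numerical diffusion at large Péclet numbers). The
stationary density comes from a single sparse null-space solve with one
flux-balance equation replaced by the normalization constraint — direct
time-marching would converge only on the inter-well mixing time, which is
exponentially long at small noise. A marching helper (implicit Euler on the
same conservative operator, mass-conserving to solver round-off) is
provided for validation.

Modality is counted on the Gaussian-smoothed density (width 2 cells) as
local maxima exceeding 5 % of the global maximum — robust against
Monte-Carlo roughness, matched to the visual bimodal/unimodal distinction.

The histogram/FPK L1 cross-check uses γ = 0.3, where the well-hopping time
(~20) is far below the total simulated time, so the empirical well weights
equilibrate; at smaller noise the histogram's split between wells is set by
initial conditions rather than ergodic averaging (the generator seeds both
wells equally in bistable runs for exactly this reason).

## What the synthetic data does and does not emulate

The generators produce exactly the study's inputs: stable-law increments,
deterministic ring lattices, and basin-resolved initial ensembles. They do
not emulate heterogeneous parameters across nodes, correlated or colored
noise, rewired/random graphs, or measurement noise on trajectories —
passing tests therefore speak to the idealized homogeneous-ring model, not
to robustness against those real-data features.

## Numerical choices and degenerate inputs

- Equilibria: closed form; `critical` regime reported when
  |e − a/b| < 10⁻¹²; equilibrium residual tolerance 10⁻⁸.
- Stability at a non-equilibrium point: computed formally with a warning.
- Switch detection on a path that never reaches either threshold: empty
  record; dwell statistics with < 2 switches: empty summary (NaN means).
- All-censored MFPT/NMFPT estimates are flagged (`valid` / `all_censored`)
  and never silently dropped.
- PDE solvers report residuals; non-decayed survival integrals are flagged
  or raise.

## Problem sizes

Default experiment sizes (500 Monte-Carlo paths per MFPT point, 32–50 units
per density/switching ensemble, 50 realizations of an N = 100 ring per
NMFPT cell, horizons 100–1000) were chosen so every sweep resolves its
trend several standard errors clear of noise; the test suite uses the same
sizes for the headline checks and smaller ones for structural checks.

## Known limitations

- Lévy regimes α < 2 are supported by the generator and the Monte-Carlo
  route but not by the PDE solvers (no fractional-Laplacian discretization).
- No adaptive time stepping or higher-order stochastic schemes; exit-time
  estimates at the default dt carry the O(√dt) monitoring bias noted above.
- The hysteresis thresholds ±1 and coupling strengths d₁ = d₂ = 0.1 are
  conventions of this package (exposed in every config); switching counts
  and NMFPT values depend on them quantitatively, though the reported
  trends are robust to moderate changes.
- Marginal (zero-coefficient) stability is flagged, not resolved by
  higher-order analysis.
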