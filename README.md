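# fhnswitch

Noise-induced switching between the resting and firing states of the
bistable FitzHugh–Nagumo (FN) neuron — for computational neuroscientists and
systems biologists studying how stochastic forcing and network topology
toggle a bistable unit between its attractors (a minimal model of short-term
memory maintenance and loss).

## The model

A single unit follows

```
du/dt = c (e u − u³/3 − v) + ξ(t)
dv/dt = c (a u − b v)
```

with membrane potential `u`, recovery variable `v`, positive constants
`a, b, c`, excitability `e`, and an α-stable driver `ξ` (α = 2: Gaussian
noise of scale γ, noise strength `d = γ^α`). The deterministic system has a
supercritical pitchfork at `e = a/b`: for `e > a/b` two stable equilibria
`(±√(3(e − a/b)), ±a u₀/b)` flank an unstable origin, and the Routh–Hurwitz
conditions `c₁ = cb − ce + cu₀² > 0`, `c₀ = cb(cu₀² − ce) + ac² > 0` decide
stability. Noise drives transitions between the two wells; the package
quantifies them through

- **switch counts and dwell (retention) times** (two-threshold hysteresis),
- the **mean first passage time** (MFPT) from a well to a threshold, by
  Monte Carlo and independently by the backward Fokker–Planck survival
  probability `T(x) = ∫₀^∞ G(x, t) dt`,
- the **stationary density** p(u, v) (long-run histogram and stationary
  forward Fokker–Planck solve) and its modality,
- the **network MFPT (NMFPT)** on K-nearest-neighbour ring lattices with
  diffusive Laplacian coupling, swept over noise scale γ and clustering
  coefficient `cc = 3(K−2)/(4(K−1))`.

See `docs/methods.md` for the numerical methods and conventions.

## Worked example

```python
import numpy as np
from fhnswitch import (FNParams, PassageProblem, SimConfig, StableNoiseSpec,
                       build_ring_lattice, find_equilibria, mfpt_monte_carlo)

params = FNParams(a=2.0, b=1.5, c=1.0, e=2.0)
eq = find_equilibria(params)
print(f"regime: {eq.regime}")
for pt, stable in zip(eq.points, eq.stability_flags):
    print(f"  u0 = {pt.u:+.4f}, v0 = {pt.v:+.4f}, stable = {stable}")

start = eq.stable_points[0]            # the resting state (-1.414, -1.886)
for gamma in (0.2, 0.3, 0.4):
    prob = PassageProblem(params, StableNoiseSpec(gamma=gamma), tuple(start), u_high=1.0)
    est = mfpt_monte_carlo(prob, SimConfig(dt=0.01, t_end=1000.0, seed=1), n_paths=200)
    print(f"gamma = {gamma:.2f} (d = {gamma**2:.2f}): MFPT = {est.mean:6.1f} +/- {est.sem:.1f}"
          f"  (censored {est.censored}/{est.n_paths})")

for k in (2, 14, 20, 36):
    print(f"k = {k:2d}: cc = {build_ring_lattice(100, k).clustering:.4f}")
```

prints

```
regime: bistable
  u0 = -1.4142, v0 = -1.8856, stable = True
  u0 = +0.0000, v0 = +0.0000, stable = False
  u0 = +1.4142, v0 = +1.8856, stable = True
gamma = 0.20 (d = 0.04): MFPT =   87.4 +/- 5.5  (censored 0/200)
gamma = 0.30 (d = 0.09): MFPT =   18.8 +/- 1.1  (censored 0/200)
gamma = 0.40 (d = 0.16): MFPT =    9.8 +/- 0.6  (censored 0/200)
k =  2: cc = 0.0000
k = 14: cc = 0.6923
k = 20: cc = 0.7105
k = 36: cc = 0.7286
```

The three equilibria confirm bistability at `e = 2`; the escape time from
the resting well drops sharply as the noise scale grows — stronger stimuli
toggle the stored state faster — and the four lattices realise the
clustering coefficients used in the network sweeps.

## Command line

Each experiment family is a subcommand writing CSV tables plus a JSON
manifest (config echo, seeds, version, wall time):

```
fhn bifurcation   --seed 1 --out out/bif
fhn mfpt-curve    --seed 1 --out out/mfpt
fhn density       --seed 1 --out out/density
fhn switch-single --seed 1 --out out/switch
fhn switch-network --seed 1 --out out/net
fhn nmfpt-surface --config my_sweep.yaml --out out/surface
```

Flags override YAML config values; all parameters (kinetics, noise,
coupling, lattice sizes, thresholds, horizons, repetition counts) are
exposed.

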