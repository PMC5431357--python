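# loopwaves

Emergent waves in a stochastic birth–death–migration process on directed
loop networks: an exact simulator, a master-equation oracle, and the
piecewise-smooth mean-field analysis of the wave/collapse bifurcations.

## The problem

How can a coherent, persistent, travelling disturbance emerge in a system
that is discrete everywhere and whose microscopic dynamics are entirely
memoryless and incoherent? `loopwaves` studies the minimal stochastic model
with that property: particles on a closed loop of *N* nodes (the interesting
physics already appears at *N* = 3), subject to three elementary processes:

* **migration** — each particle hops to an adjacent node at rate *r*, forward
  (node *i* → *i*+1) with probability (1 + *ρ*)/2 and backward with
  (1 − *ρ*)/2, where −1 ≤ *ρ* ≤ 1 is the directional bias;
* **local births** — each particle gives birth at rate *μ*, so node *i* gains
  a particle at rate *μ nᵢ*;
* **global deaths** — particles are removed from the whole system at total
  rate *μ n*_tot, drawn with equal probability from each *populated* node
  (rate *μ n*_tot/*Z* per populated node, *Z* = number of populated nodes).
  The global death channel is the only non-local ingredient — it plays the
  role a field plays in continuum theories.

The total population is then a critical birth–death process: it fluctuates
but is conserved in mean. The mean populations live on the simplex
Σ⟨*nᵢ*⟩ = n̄ and obey the linear flow d⟨**n**⟩/dt = ⟨**n**⟩**B** in its
interior (row-vector convention throughout), with eigenvalues

σ_k = μ − r + r cos(2πk/N) + i rρ sin(2πk/N),  k = 1…N−1,

so the uniform state loses stability in a Hopf bifurcation at
μ* = r(1 − cos 2π/N) — equal to (3/2) r at N = 3. On the simplex boundary
(one node empty) the dynamics become a Filippov sliding mode: blending the
interior and boundary generators with the weight w = Pr{n_empty > 0} gives
the scalar sliding law

d*x*/dt = (rρθ/2)(*x* − κ_e),  κ_e = ½(1 − 1/θ),  κ_b = ½(1 + θ/3),

for the lead-node fraction *x*, where **θ = (2μ − 3r)/(rρ)** is the single
control parameter. Sliding is admissible up to κ_b (the exit point) and has
an unstable equilibrium at κ_e. Four phases result:

| regime | condition | behaviour |
|---|---|---|
| amorphous | θ < 0 | uniform spread, fluctuations decay |
| wave | 0 < θ < θ_c | a rotating limit cycle: nodes empty and refill in sequence |
| intermittent | 1 < θ < θ_c | stochastic switching between wave and single-node lodging |
| collapsed | θ > θ_c | bulk of the particles lodge at one node |

θ_c solves l(θ_c/√3) + π/6 = 0 with l(x) = log(x)/x, numerically
**θ_c ≈ 1.2037**: at that point the limit cycle grazes the unstable boundary
point κ_e and the wave ceases to exist. The wave frequency scales as
f = rρ·f̂(θ) with f̂ ∼ −1/log|θ − θ_c| near threshold.

## What the package provides

* `loopwaves.model` — parameters, rate matrices, closed-form spectra,
  thresholds (κ_b, κ_e, θ, θ_c-related quantities).
* `loopwaves.gillespie` — exact direct-method stochastic simulation
  (numba-compiled core, bit-reproducible per seed) and ensembles.
* `loopwaves.master` — the exact master equation on a truncated population
  lattice with honest leakage accounting; the ground-truth oracle for the
  simulator at small populations.
* `loopwaves.meanfield` — the hybrid deterministic system: closed-form
  interior spirals, analytic boundary sliding, event-driven integration,
  Poincaré-map limit cycles, frequency/amplitude curves, θ_c.
* `loopwaves.trajstats` — regime classification and frequency/amplitude
  estimation from trajectories (winding of the leading-node label).
* `loopwaves.cli` — a `loopwaves` command with `simulate`, `ensemble`,
  `meanfield`, `master-eq`, `classify`, `sweep` and `theta-critical`
  subcommands, YAML configs, and scenario presets (`amorphous`, `wave`,
  `intermittent`, `collapsed`).

## Worked example

```python
import loopwaves as lw

print(f"theta_c = {lw.theta_critical():.4f}")

p = lw.ModelParams(r=1.0, rho=1.0, mu=1.8)
print(f"theta   = {lw.control_parameter(p):.2f}")

wc = lw.limit_cycle(p)
print(f"mean-field wave: period {wc.period:.3f}, f = {wc.frequency:.4f}, "
      f"A = {wc.amplitude:.3f}")

traj = lw.simulate(p, [1000, 1000, 1000], t_max=100.0, seed=1)
print(f"simulated regime: {lw.classify(traj).label}")
f, f_sd = lw.estimate_frequency(traj)
A, A_sd = lw.estimate_amplitude(traj)
print(f"estimated f = {f:.4f} +/- {f_sd:.4f}, A = {A:.2f} +/- {A_sd:.2f}")
```

prints

```
theta_c = 1.2037
theta   = 0.60
mean-field wave: period 9.034, f = 0.1107, A = 2.428
simulated regime: wave
estimated f = 0.1176 +/- 0.0114, A = 2.30 +/- 0.26
```

At θ = 0.6 the deterministic cycle completes a revolution every ≈ 9 time
units with its node populations peaking at ≈ 2.4× the mean per-node
population; a stochastic run with 1000 particles per node is classified as a
wave and reproduces both numbers within the estimator spread (demographic
noise lifts trajectories off the boundary slide slightly early, so the
measured frequency sits a little above — and the amplitude a little below —
the deterministic values).

The same from the shell:

```sh
loopwaves simulate --scenario wave --seed 1 --outputs runs/wave
loopwaves sweep --thetas 0.3,0.6,0.9,1.1 --outputs runs/sweep
```

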