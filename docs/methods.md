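# Methods

## Model and conventions

The state of the system is the integer vector **n** = (n₀, …, n_{N−1}) of
node populations on a directed loop. Events and rates, per node *i*:

| event | rate | effect |
|---|---|---|
| forward migration | r nᵢ (1 + ρ)/2 | nᵢ −1, n_{i+1} +1 |
| backward migration | r nᵢ (1 − ρ)/2 | nᵢ −1, n_{i−1} +1 |
| birth | μ nᵢ | nᵢ +1 |
| death | μ n_tot / Z if nᵢ > 0, else 0 | nᵢ −1 |

Z is the number of populated nodes, recomputed from the state at every use
(never cached). Total birth and death rates are both μ n_tot, so n_tot is a
critical linear birth–death process: conserved in mean, fluctuating in
realizations, with extinction reachable. Extinction is a valid absorbing
outcome, not an error; trajectories are truncated there and flagged.

All mean-field matrices act on **row vectors** (d⟨n⟩/dt = ⟨n⟩B), matching
the orientation in which row *i* carries the rates out of node *i*. Node
indexing is 0-based and "forward" is i → i+1 (mod N), so ρ = 1 is a pure
forward cycle. ρ < 0 is equivalent to reversing the node order; mean-field
routines handle it by that mirror symmetry, and the regime structure depends
on |θ|.

### Parameters

* **r** (> 0): migration rate per particle per unit time. Sets the basic
  time scale; rρ is the coherent drift rate and scales all wave
  frequencies.
* **ρ** (∈ [−1, 1]): directional bias. ρ = 0 has purely real spectra and no
  oscillatory regime (the control parameter is undefined there and the code
  says so rather than returning ±∞).
* **μ** (≥ 0): birth rate = per-capita share of the global death rate.
* **N** (≥ 2): loop size. Wave analysis requires N ≥ 3; boundary
  (sliding-mode) analysis is implemented only for N = 3 and is *refused*
  for larger loops rather than guessed — the boundary equations depend on
  which subsets of nodes are populated and have only been derived for the
  three-node case. Interior spectra, Hopf thresholds and simulation support
  any N.

## Stochastic engine

Direct-method Gillespie (exponential waiting time at the total rate,
categorical event choice), exact for the Markov process; no tau-leaping or
diffusion approximation is offered since the claims of interest rest on
exactness and populations ≤ ~10⁵ are tractable. Two engines share the event
semantics: a numba-compiled kernel for long runs and a pure-Python reference
path (numpy `Generator`) used when an event log is requested. Each is
bit-reproducible given (params, initial, seed); they consume different RNG
streams, so they agree in distribution rather than path-by-path. Replicate
*k* of an ensemble uses seed_base + *k*. Sampling is piecewise-constant: the
state recorded at a grid time is the state immediately before it. Ensemble
moments count extinct replicates as the true all-zero state, which is what
makes the conserved-mean-total property hold across the full ensemble.

## Master-equation oracle

The lattice of configurations with n_tot ≤ n_max (K = C(n_max + N, N)
states) carries the generator whose off-diagonals are exactly the simulator
propensities — the two are compared entry-by-entry in the tests, and the
simulator's empirical distributions are validated against the propagated
distribution by total-variation distance. Because the total population is
unbounded, truncation is handled sub-stochastically: births that would leave
the lattice keep their rate in the diagonal but have no destination, so
probability mass decays at exactly the leak rate and the lost mass is
tracked (`leaked`); probability + leaked = 1 to solver tolerance. Tests
choose n_max so that leaked ≤ 10⁻⁶ (the total-population tail is bounded by
the critical birth–death tail, ≈ (t/(1+t))^{n_max} per ancestor).
Propagation is by matrix exponential: dense `expm` for K ≤ 2000, Krylov
`expm_multiply` above — a contract, not a mechanism; results agree to
tolerance.

## Mean-field hybrid system

Interior segments use the exact closed-form spiral: the deviation from the
uniform point is a single complex Fourier mode of the circulant generator,
m_j(t) = n̄/3 + 2 Re[c₁ e^{(λ−iω)t} e^{2πij/3}] with λ = μ − (3/2)r and
ω = (√3/2) rρ. This was cross-checked against `scipy.linalg.expm` on random
parameters (agreement ≤ 10⁻¹⁰). Boundary-hit times are found by scanning at
2048 points per rotation and polishing with bracketed root-finding
(xtol 10⁻¹³); the scan starts one step after t = 0 because a boundary
departure is tangential (the empty component leaves quadratically, since the
Filippov weight is exactly 1 at the exit point κ_b).

On a boundary the empty component is pinned to exactly 0 (snap tolerance
10⁻⁹·n̄) and the lead fraction follows the affine sliding law
dx/dt = a x + b with a = μ − (3/2)r and b = −a κ_e, written without θ so it
stays finite at θ = 0. Slide durations are analytic (logarithms of rate
ratios), so region switches introduce no integration error; simplex
conservation along hybrid trajectories is at rounding level. The sliding law
was re-derived independently from the weighted combination of the interior
and boundary generators and is asserted against that blend numerically.

The limit cycle is located by iterating the boundary-to-boundary Poincaré
map. Because sliding exits always occur exactly at κ_b, the map is constant
after the first slide and the iteration converges immediately; the generic
iteration (tolerance 10⁻⁹) is kept for the no-slide case (arrival above
κ_b) and as a consistency check. One cycle = three congruent segments by the
cyclic symmetry; frequency counts full revolutions (f = 1/period), and
f̂ = f/(r|ρ|) depends on θ alone (asserted across parameter scalings).

**Amplitude convention.** A = (cycle maximum of one node's population)/(n̄/3),
so A = 1 at the uniform state and A → 3 at full collapse. The mean per-node
population n̄/3 is used as the reference because it makes the convention
exact at both ends; the cycle maximum is refined parabolically from 4096
samples per segment.

Degenerate θ exactly at 0 or θ_c (non-hyperbolic cases) report
`exists=False` with a `marginal` flag instead of attempting the computation.

θ_c is computed by bracketed root-finding of log(x)/x + π/6 = 0,
x = θ/√3, on (1, √3) (xtol 10⁻¹²) ≈ 1.2037. Two independent consistency
checks are tested: the grazing continuation (the θ at which the cycle's
boundary arrival meets κ_e) reproduces the same number, and 1/f̂ grows
linearly in −log(θ_c − θ) with slope 6/θ_c — the slide segments dominate the
period near threshold, each contributing (2/θ) log(1/(x_arr − κ_e)).

## Trajectory observables

All observables work on occupancy fractions nᵢ/n_tot, making them invariant
under cyclic relabelling and population rescaling. The phase of the rotating
disturbance is the *winding* of the leading-node (argmax) label: forward
hand-overs count +1, backward −1, so flicker between neighbours cancels;
three net steps are one revolution.

* **Frequency**: revolutions per unit time, measured between the first and
  last hand-over inside each of 5 equal windows (measuring hand-over to
  hand-over removes the edge-truncation bias a raw per-window count would
  have). An estimate requires ≥ 1.5 net revolutions *and* directional
  coherence ≥ 0.5 (fraction of hand-overs in the majority direction) —
  an amorphous argmax random-walks with coherence ~ 1/√steps (measured
  ≤ 0.22 versus ≥ 0.69 for waves at 300/node), so the threshold separates
  the two regimes with a wide margin.
* **Amplitude**: per-cycle maxima of one node's fraction, times 3, with
  cycles delimited by successive full revolutions.
* Both estimators expose the raw per-window / per-cycle arrays
  (`window_frequencies`, `cycle_amplitudes`), so within-realization and
  across-realization spreads can both be reported; `estimate_*` return the
  mean and standard deviation of those estimates.

**Classifier.** Collapse epochs are maximal stretches with leading occupancy
above 0.9 lasting at least one wave period (the mean-field period when the
cycle exists, else the linear rotation period 2π/ω) — the dwell requirement
stops large-amplitude wave peaks from counting. If collapse epochs exist,
the label is `intermittent` when a full revolution occurs after the first
epoch (or two before it — a wave that later locked), else `collapsed`.
Without collapse epochs: `wave` when ≥ 2 net revolutions occur and nodes
empty (fraction < 0.05) recurrently, else `amorphous`. The 0.9/0.05
thresholds are exposed as arguments.

## What the tests do and do not show

The package generates all of its own data; there is no external input. The
stochastic tests therefore validate the implementation against its own exact
oracle (master equation, closed forms, conservation laws) and the
deterministic analysis against scaled-down ensembles — they demonstrate
internal consistency of the model's three descriptions (jump process, master
equation, mean field), not anything about a particular natural system. Two
systematic finite-size effects are visible at the test scales and are
genuine physics, not estimator artefacts: noise lifts trajectories off the
boundary slide before κ_b, so stochastic waves run slightly fast and
slightly small compared with the deterministic cycle (at 3000 particles per
node: ~ +5 % in f, ~ −10 % in A), and the intermittent window produces
wave-presenting realizations at small populations, so classification there
is only required to be wave-or-intermittent. Both effects shrink as
populations grow.

## Problem sizes

Desk-scale defaults keep every computation light: master-equation lattices
up to n_max = 28 (K = 4495 states), regime studies at 300 particles per node
for 100 time units over 5 seeds, wave-curve ensembles at 3000 particles per
node for 80 time units over 10 replicates, and oracle comparisons at 10⁴
replicates of a three-particle system. The whole suite runs in well under a
minute on one core.

## Known limitations

* Boundary mean-field analysis (and hence limit-cycle computation) only for
  N = 3; larger loops are simulated exactly but analysed only through the
  interior spectrum.
* No higher-order (fluctuation) corrections to the mean field: the
  intermittent regime's switching statistics are observed, not predicted.
* The amplitude and frequency of the stochastic wave are estimated from the
  argmax winding; for extremely weak waves just above θ = 0 with small
  populations the coherence gate may reject short trajectories.
* Closed-form transcendental expressions for A(θ) and f̂(θ) are not
  implemented; both are computed by numerical continuation of the hybrid
  cycle and validated against the threshold condition and the logarithmic
  frequency asymptote.
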