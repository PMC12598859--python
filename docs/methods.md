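# Methods

Model definitions, numerical methods, and validation notes for the
`localft` package.  Reduced (WCA) units throughout: ε = σ_WCA = m = 1,
k_B = 1.

## 1. Model

### Fluid and driving

N particles in a 2D periodic box interact through the WCA potential
(truncated–shifted Lennard-Jones, cutoff 2^{1/6}, purely repulsive).
Half the particles carry color charge c_i = +1, half −1; a uniform color
field exerts `c_i F_e e_x`.  The dissipative flux is the color current
`J_x = Σ_i c_i p_{x,i}` and the dissipation function over duration t is

```
Ω_t = β F_e ∫₀ᵗ J_x ds            (deterministic driving)
```

with β = 1/T = 1.  The *local* dissipation restricts the sum to
particles currently inside a region (slab or grid cell); a particle
contributes to whichever region contains it at each instant, so the
regional integrals tile exactly: `Σ_regions Ω_{region} = Ω_total` (to
1e−9 relative, enforced in tests).

### Scenarios

* **channel** — box 50.6 × 14, F_e = 0.3, 164 fluid particles.  Two
  tethered single-layer WCA walls (harmonic tethers, k = 100, site
  spacing 1 along x) trace the profile `y = L_y/2 ± W(x)/2` with
  `W(x) = W₀ − 2a sin²(πx/L_x)`, W₀ = 10, a = 2.5: the channel is
  narrowest at the box center.  Only wall particles are thermostatted
  (isokinetic), so heat generated in the fluid is conducted out through
  the walls.  Periodic in x only.
* **obstacle** — box 30 × 30, F_e = 0.3, 400 fluid particles, fully
  periodic.  A fixed disk of radius R = 5 at the box center repels fluid
  through WCA evaluated on the shifted distance d = r − R.  Thermostat:
  an *ergostat* — a Gaussian multiplier that keeps the total energy
  H = KE + U constant, removing heat at exactly the rate the field does
  work.
* **active** — box 22 × 22, F_e = 0.05, 242 fluid particles, fully
  periodic.  Each particle additionally carries an Ornstein–Uhlenbeck
  propulsion variable ξ_i acting along x:

  ```
  dξ_i = −ξ_i/τ dt + (σ/√τ) √2 dW ,   τ = 0.1,  σ = 2 F_e = 0.1
  ```

  (stationary standard deviation exactly σ).  All fluid particles are
  isokinetically thermostatted.  The dissipation acquires a second,
  stochastic component:

  ```
  Ω_t = β F_e ∫ J_x ds  +  β ∫ Σ_i ξ_i p_{x,i} ds .
  ```

  Both components are accumulated per region, and either can be analyzed
  alone (the package exposes `omega_fe` and `omega_xi` per bin).

Density is ρ ≈ 0.5 in all scenarios (fluid particle count from the
accessible area).  ρ, T, and N are implementation choices fixed before
any statistics were collected; κ at fixed L depends on them (see §5).

### Isokinetic and ergostat multipliers

The Gaussian isokinetic thermostat applies `−α p_i` to the thermostatted
subset S with

```
α = Σ_{i∈S} p_i·F_i^{tot} / Σ_{i∈S} p_i²,
```

where `F_i^tot` includes the WCA, tether, color, and (active scenario)
ξ forces — the constraint only holds when α sees exactly the forces in
the equation of motion.  The ergostat multiplier instead balances the
field's power: `α = β F_e J_x / (2 KE)` (scaled so dH/dt = 0 exactly).

## 2. Integration

Operator-split, time-reversible second-order scheme, timestep 0.005
(0.001 for the reversibility checks):

1. half OU update of ξ (exact propagator
   `ξ' = ξ e^{−dt/τ} + σ√(1−e^{−2dt/τ}) G`),
2. constrained half kick,
3. full drift,
4. constrained half kick,
5. half OU update.

**Constrained kick (isokinetic).**  The implicit-midpoint discretization
of the constrained half-kick admits a closed-form solution: writing the
update as `p' = s(p + Δ)` with the scalar s fixed by the kinetic-energy
constraint, s solves a scalar quadratic.  The constraint is then exact
to machine precision every half-step; the measured kinetic-energy drift
is ~1e−15 per step (acceptance bound 1e−10).

**Constrained kick (ergostat).**  The energy constraint couples the
kick to the *potential at the end of the drift*, so a naive first
half-kick (targeting KE = H₀ − U(q_n)) is a no-op and destroys
reversibility.  The first half-kick instead targets the
midpoint-anchored value `2(H₀ − [U(q_n) + U(q_{n+1})]/2)` via a short
fixed-point iteration (≤ 6 iterations to relative tolerance 1e−13); the
second half-kick targets `2(H₀ − U(q_{n+1}))`.  Forward and
momentum-reversed backward integration are then exact mutual inverses:
measured position mismatch 2e−14 after t = 5, `Ω_fwd + Ω_rev ≈ 1e−14`,
relative energy drift 2e−15.

**Time reversibility** is checked directly in the test suite for both
thermostats: integrate forward for t = 0.5, reverse momenta, integrate
forward again, and recover the initial condition to 1e−6 with
`Ω → −Ω` (and `|Ω| > 1e−3`, so the check is not vacuous).

Forces use numba-compiled linked-cell neighbor search (rebuilt every
step), with an O(N²) fallback for boxes under four cells across; the
pure-Python reference implementations in `interactions.py` are the
oracles the kernels are tested against.

## 3. Equilibration and ensemble protocol

Transient-trajectory ensembles start from equilibrated (F_e = 0,
ξ = 0) configurations:

* one field-free run with an all-particle isokinetic thermostat,
  burn-in 50 time units, then snapshots every 5 time units (100
  snapshots per ensemble);
* trajectory i starts from snapshot `i mod 100` with **fresh**
  Maxwell–Boltzmann momenta (exactly rescaled to T = 1 on the
  thermostatted subset, center-of-mass momentum removed in periodic
  scenarios) and, in the active scenario, fresh stationary ξ;
* trajectory i uses an independent RNG stream
  (`SeedSequence(base).spawn`-style keying), so ensembles are exactly
  reproducible and resumable.

Snapshot reuse was checked for bias: decomposing Cov(Ω*, Ω_L) into
between-snapshot and within-snapshot parts on a 3000-trajectory active
ensemble gives a *slightly negative* between-snapshot contribution, so
the measured κ is not an artifact of shared initial configurations.

Durations: t = 3 (active), t = 5 (channel, obstacle).

## 4. Statistics

* **κ estimator** — `κ̂ = Cov(Ω*, Ω_L)/Var(Ω_L)` (sample covariance),
  standard error from a seeded bootstrap over trajectories (default
  1000 resamples).
* **Asymmetry function** — symmetric histogram bins `±(k·w ± w/2)` with
  Freedman–Diaconis width on pooled |Ω| by default; points
  `A_k = ln(n₊/n₋)` with error `√(1/n₊ + 1/n₋)`; both sides must reach
  a minimum occupancy of 10.  The slope is an origin-constrained
  weighted least-squares fit (the relation forces A(0) = 0).
* **Local-FT check** — `slope` vs `1 + κ̂` compared at three combined
  standard errors (`√(SE_slope² + SE_κ²)`).
* **Gaussian fixtures** — for Gaussian dissipation with mean μ and
  variance v the asymmetry slope is exactly `2μ/v`; fixtures draw
  FT-consistent pairs (μ = v(1+κ)/2) with prescribed κ, giving a
  closed-form oracle for the entire estimation chain (e.g.
  κ ∈ {−0.36, 0, 0.82} → slopes {0.64, 1.0, 1.82}, recovered within
  3 SE at n = 10⁵ in the tests).
* **Near-global histograms** — for a bin covering 80% of the channel
  the negative tail holds < 1% of trajectories; the headline script
  uses a fixed width of 1.5 (≈ sd/3.5) with a pre-registered escalation
  ladder 1.5 → 2.5 → 4.0 if the minimum occupancy is not met.  Width
  affects error bars, not the slope systematically.

## 5. Validation summary and known limitations

Verified in the test suite (exact tolerances in
`tests/test_acceptance.py`):

* isokinetic constraint ≤ 1e−10 per step; ergostat |ΔH|/|H| ≤ 1e−8 over
  t = 5; regional partition and component decomposition identities to
  1e−9;
* time reversibility with Ω → −Ω at 1e−6;
* F_e = 0 gives Ω ≡ 0 identically; driven runs give ⟨Ω⟩ > 0 at ≥ 5 SE
  (second-law behavior); the global dissipation in the strongly driven
  channel has negligible negative mass (< 2%) while a narrow slab
  retains a large negative tail (> 10%);
* forces against central-difference oracles; kernels against the
  pure-Python reference; OU stationary statistics exact.

Measured phenomenology at these parameters (n = 3000 exploration
ensembles, active fluid L = 2.2 unless noted):

* self-consistency `slope = 1 + κ̂` holds at every analyzed width in the
  active fluid (z ≤ 1.3) and globally (slope 0.97 ± 0.05);
* κ decays monotonically with L: 0.30, 0.15, 0.07 at L = 2.2, 4.4, 6.6;
  in the channel: 0.80 at L ≈ 2 falling to 0.03 at 0.8 L_x;
* the active fluid's total-dissipation slope at L = 2.2 is
  1.35 ± 0.11 — consistent with its own 1 + κ = 1.30, but the point
  estimate sits above 1 because κ = 0.30 at this density;
* the stochastic-component slope at L = 2.2 is 1.11 ± 0.14 (its κ is
  *positive* here, +0.16).

**Limitations.**  (i) κ at fixed L is a strong function of density and
system size; the values above are specific to ρ = 0.5 and the box sizes
listed.  (ii) The local relation assumes a region inside a
*homogeneous* system.  In the channel it holds in slabs away from the
constriction (e.g. slope 1.80 vs 1 + κ = 1.78) but fails inside the
constriction (slope ≈ 1.1 vs predicted ≈ 1.8–2.0), where density and
dissipation vary strongly across the slab; channel-wide statements are
therefore restricted to the near-global bin.  (iii) Headline ensembles
(4000–6000 trajectories) give ~3–10% relative slope errors; rare-event
tails (near-global negative events) are the binding statistical cost.
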