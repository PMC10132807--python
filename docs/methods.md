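# Methods

## Model

`ompsim` simulates activity-dependent myelin plasticity along a bundle of
`N_A` axons myelinated by a chain of `N_O` "effective oligodendrocyte"
segments.  An effective segment stands for the population of
oligodendrocytes at one location that sees the same spike pattern and
responds identically; it is governed by one set of equations.

Three coupled processes act at each segment:

1. **Global signal.**  Every spike on any myelinated axon releases a fixed
   quantity `Q = 1` of a fast global factor whose concentration `G(t)`
   (units 1/ms) follows the impulse-response kernel

       R(t) = Q (τr + τd)/τd² · e^(−t/τd) (1 − e^(−t/τr)),   t > 0,

   normalized so that ∫R dt = Q.  With a single characteristic time
   τr = τd = τG this is (2/τG) e^(−t/τG)(1 − e^(−t/τG)), peaking at
   τG·ln 2 with height 1/(2τG).  G is the shared timing reference: its
   value at the moment of a spike encodes how close that spike is to the
   recent activity of the whole bundle.

2. **Local myelin-promoting factor.**  Each spike on axon `a` releases
   factor in proportion to the instantaneous global signal,
   `ΔM_a = λM · G(t_spike)`; between spikes `M_a` decays at the conversion
   rate λA as it is turned into myelin.  Time-locked axons that lag behind
   their group catch the response tails of the earlier spikes, so lagging
   axons accumulate more factor — the core of the synchronizing mechanism.

3. **Delay learning.**  The local conduction delay τa(o) shortens with
   myelin addition and lengthens with removal,

       dτa/dt = λR F_sR(τa) − λA F_sA(τa) M_a(t),

   where F_sA(τ) = (τ − τmin)/(τmax − τmin) and F_sR(τ) = (τmax − τ)/(τmax
   − τmin) are normalized saturation ramps vanishing at the attainable
   bounds.  The removal rate λR is regulated homeostatically toward a
   nominal total delay: dλR/dt = λH λR (τnom − ⟨τ⟩).

The **instantaneous-myelination** variant takes λA → ∞: the factor
equation drops out and each spike directly shortens the delay by
`λM F_sA(τa) G(t_spike)`.

A **chain** routes each physical spike segment to segment: arrival at
segment o+1 equals arrival at segment o plus the local delay read at that
arrival instant.  Total conduction delay per axon is the sum of local
delays; per-segment bounds and nominal delays are the whole-axon values
divided by `N_O`, so the attainable whole-axon band is independent of
chain length.

**Synchrony metric.**  Fixed (non-modifiable) source-side delays `D_a`
with spread σD disperse the spikes as they enter the bundle; the arrival
spread στ = SD_a(D_a + Σ_o τa(o)) (population SD) is recorded at every
epoch boundary, giving the synchronization profile στ(t) with στ = 0
meaning perfect synchrony.

## Default parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| τG | kernel rise/decay time | per run (2–100) | ms |
| λM | factor production rate | 0.02 | 1/ms |
| λA | myelin conversion rate | 0.1 | 1/ms |
| λH | homeostatic rate | 0 (off) | 1/ms² |
| λR(0) | initial removal rate | λM·N_A/τs² | 1/ms |
| τmin, τmax | attainable whole-axon delay bounds | 3, 100 | ms |
| τnom | nominal (homeostatic) delay | 50 | ms |
| τs | mean inter-spike interval | 100–200 | ms |
| σD | fixed-delay spread | 10 | ms |
| σj | spike-time jitter SD | 0–3 | ms |
| pτ | initial adaptive-delay spread | 5 | % |
| T_exp, n_e | learning duration, epochs | 6×10⁵ ms, 50 | |

λR starts at the Poisson balance value λM·N_A/τs², which makes removal
and spike-driven addition cancel exactly when the delays sit at the
mid-point of the saturation band; away from the mid-point the ramps tilt
the balance, which is why measured λR equilibria deviate from the formula
under saturation.  When several signal groups have different τs, the
balance value uses the group-mean τs.

## Spike synthesis

Inter-spike intervals are drawn from either a refractory Poisson law
(ISI = t_R + Exponential with mean τs − t_R, preserving mean ISI = τs so
the firing rate is comparable across refractory settings) or a regular
grid at τs.  Time-locked groups share one base train; each axon sees it
shifted by its fixed delay, so the fixed delays are realized in the spike
times themselves and the router adds no further source offset.  Gaussian
jitter N(0, σj) is applied per spike, independently across axons even
within a locked group; jittered spikes may reorder (re-sorted) or violate
refractoriness (kept), and spikes jittered outside the simulation window
are dropped.  Fixed delays are drawn N(0, σD), mean-centered and rescaled
so their population SD equals σD exactly.

Per-axon rate heterogeneity (σs > 0) draws each axon's τs once per run
from N(τs, σs·τs/100).  For time-locked groups this is realized by
time-rescaling the shared base train per axon, which preserves each
axon's renewal law while letting the locking drift apart progressively;
the default is σs = 0.

One master seed feeds a `SeedSequence` tree with one child stream per
axon (plus one per group), so identical seeds give bit-identical
schedules and enlarging a bundle never perturbs existing trains.

## Numerics

* **Global signal, exactly.**  The kernel is the impulse response of a
  second-order linear system written as (G, v = dG/dt) with
  dv/dt = −ab·G − (a+b)v, a = (τr+τd)/(τrτd), b = 1/τd.  Its eigenvalues
  −a, −b are distinct for every τr > 0 (a − b = 1/τr), so between spikes
  the state is advanced with the closed-form two-exponential propagator —
  no integration error beyond floating point.  A spike adds
  q_s = Q(τr+τd)/(τrτd²) to v; G is continuous across spikes because
  R(0) = 0, so a spike never sees its own release.  The event-driven path
  is tested against direct superposition of kernels over all past spikes.

* **Slow variables between spikes.**  M decays in closed form.  The delay
  equation's only nonlinearity is the piecewise-linear ramps, so one
  midpoint sub-step with the exact M integral per interval carries an
  error of order (Δτ/(τmax−τmin))² ≈ 10⁻¹⁰ per inter-spike gap — far
  below the spike-jump magnitudes.  Sub-steps shrink automatically when a
  long gap would move τ by more than 2% of the band or the homeostatic
  exponent would exceed 0.1.  λR integrates its multiplicative law
  exponentially (it cannot cross zero; a floor at 0 remains as a guard).
  Delays are clamped to [τmin, τmax] after every update as a backstop to
  the ramps, which already vanish at the bounds.

* **Event ordering.**  A single priority queue orders all segment
  arrivals by (time, segment, axon); ties at equal wall-time resolve by
  ascending segment then axon.  Delays are frozen per traversal — read
  once when the spike reaches the segment — which keeps the simulation
  causal and single-pass; the slow variables change negligibly during one
  traversal.  Spikes still in flight when the run ends are dropped.

* **Warm-up.**  With homeostasis active, two warm-up epochs run with the
  delays frozen (M and λR evolve) before στ tracking starts; στ(0) is
  recorded after initialization and fixed-delay normalization, before the
  first learning epoch.

## Profile fitting and model selection

Profiles are fitted with the nested family C (constant στ∞), E1 (single
exponential with learning time τL), E2 (double exponential), E2C
(multiplicative damped cosine) and E2C2 (additional damped additive
cosine), under box constraints tied to στ(0) and the record length
(amplitudes below 2στ(0), times between T/1000 and 1000T, oscillation
periods above T/25 and capped at 100T since longer periods are
indistinguishable from none; strict bounds nudged inward by a relative
1e−12).  Fitting is bounded trust-region least squares with analytic
Jacobians, from 50 random starts by default (log-uniform in the time
constants) plus warm starts that embed each simpler model's optimum with
the extra amplitudes switched off — which also enforces the RSS nesting
hierarchy up to optimizer tolerance.  The constant model is solved in
closed form.

Selection uses a tolerance-modified partial F-test: the denominator is
floored with RSS_min = n_pts·(pMSE·στ(0)/100)², declaring deviations
below pMSE percent of the initial spread scientifically negligible; at
pMSE = 0 the classical partial F-test is recovered exactly.  The
reference model is the minimum-MSE fit; candidates nested within it are
tested in increasing complexity and the most restricted model not
rejected at α is kept, with α ∈ {10⁻², 10⁻⁵, 10⁻¹⁰, 10⁻¹⁵} reported.
Afterwards an ad-hoc guard reverts toward the reference while the chosen
model's MSE exceeds 500× the reference's.  Ties at minimal MSE break
toward the simpler model.

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure the model is designed
for — renewal spiking with controlled correlation, rate, jitter, and
dispersion by fixed delays.  It does not emulate bursting, oscillatory or
rate-modulated drive, spike-frequency adaptation, correlated jitter, or
axon loss; passing tests therefore demonstrate the mechanism under the
stated renewal assumptions, not performance on recorded spike trains.
Chain connectivity is all-ones (every segment myelinates every axon);
partial or integer-weighted myelination matrices are validated but their
dynamics are out of scope.

## Desk-scale study conditions

Simulations in the test suite and examples are scaled to run on one CPU
in minutes; the problem sizes are the package's defaults, chosen once:

* mean-field and balance checks: N_A = 10, τs = 100 ms, T = 1.5–2×10⁵ ms;
* theory–simulation factor ratios: N_A = 2 and 5, T = 2–4×10⁵ ms,
  σj ≤ 1 ms (agreement degrades gracefully with jitter and is specified
  to hold within 10% below ~3 ms);
* selective synchronization: two 10-axon groups on an N_O = 5 chain at
  5 Hz, τG = 30 ms, σD = 5 ms, T = 6×10⁵ ms;
* chain-length stability: N_O = 1 vs N_O = 10 at 5 Hz, τG = 10 ms,
  λH = 10⁻⁶, with the single-segment run ten times longer so both
  process the same number of spikes.  The single segment re-expresses its
  fixed input lags indefinitely and overshoots the synchronized state
  (non-monotone στ); the chain's downstream segments see partially
  corrected lags and absorb the overshoot.
* synchronization endpoint grid: N_O = 10, σD = 10 ms, λM = 0.05, grid
  τG ∈ {10, 20, 30} ms × σj ∈ {1, 3} ms at 5 Hz.  At these durations
  fitted στ∞ reliably falls below 3 ms over most of the grid; resolving
  sub-millisecond endpoints (the τG = 10 ms tail) requires runs an order
  of magnitude longer than desk scale.

## Known limitations

* The delay-update magnitude λM·G has units 1/ms² acting on a delay in
  ms; the learning rate is therefore a model constant, not a derived
  physical quantity — as in the governing equations.
* Homeostatic regulation acts only on the removal rate; production (λM)
  is constant and shared, so rate heterogeneity above a few percent
  overrides synchronization (σs sensitivity).
* The instantaneous mode with large λM and active homeostasis makes the
  removal-rate equation effectively stochastic; λM must be kept small for
  stable integration there.
* Within-segment process-to-process signaling latencies (delay
  differential coupling) are not modeled.
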