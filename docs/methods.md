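# Model and methods

`presynet` simulates spontaneous activity of a cultured cortical network as
it is recorded on a microelectrode array (MEA): a population of leaky
integrate-and-fire (LIF) neurons whose **output is generated by a
presynaptic release machine** — intracellular calcium dynamics, a
calcium-dependent release-probability curve, and three interacting vesicle
pools — instead of by injected current. All activity, including the
background drive, arises from spontaneous vesicle release at resting
calcium; network bursts emerge, deplete the releasable vesicle pools, and
terminate.

## The model

**Membrane.** Each neuron's voltage (relative to rest, −70 mV) follows
τ_m dV/dt = −V + V_syn with τ_m = 52 ms, integrated on a fixed 1-ms grid by
exact exponential decay plus the step's synaptic input. Crossing θ = −30 mV
(40 mV relative) emits a spike, resets V to −77 mV (−7 relative) and starts
an absolute refractory period of 3 ms during which inputs are discarded
(not buffered — a convention; the source is silent on it).

**Synaptic input.** V_syn(i) = Σ_j A_ij · x_j · q, where x_j is the number
of vesicles neuron j released on the *previous* step (one-step synaptic
delay, so same-step updates are order-independent), q = 3.16 mV is the
postsynaptic potential per released vesicle of the pooled synapse, and A_ij
is a signed lognormal weight (negative for the 30 % inhibitory neurons),
truncated at |A| < A_max = 10.

**Calcium.** Free presynaptic calcium is rest (0.05 μM) plus a fast and a
slow residual pool. An AP sets the fast pool to 13.6 μM and adds 0.5 μM to
the slow pool (clamped at 1.36 μM). The slow pool decays by its exact
exponential factor (τ = 31 ms). The fast transient is treated as a
*sub-grid event*: its per-step retention factor is max(0, 1 − dt/τ_fast),
which is zero at the baseline τ_fast = 1 ms = dt, so an AP's fast calcium
acts for exactly one step. This reproduces the calibration the EPSP value
is built on (~1.5 vesicles released per AP: 10 vesicles × Pr 0.15); an
exact-exponential fast decay would instead release ~7 vesicles per AP
because the release curve is nearly saturated over 2–15 μM. Slower
clearance (the asynchronous-release manipulation) raises the retention
factor and prolongs the transient.

**Release probability.** Per-vesicle, per-step:
Pr(Ca) = α / (1 + e^(−β·log₁₀ Ca + γ)) + δ with α = 0.175, β = 2.35,
γ = 0.78, δ = −3.6·10⁻³, clamped to [0, 1] — a Calyx-of-Held release-rate
curve rescaled so the ceiling at maximal attainable calcium
(13.6 + 1.36 + 0.05 μM) is 0.15, the lower Pr of cortical synapses. At rest
it gives 9.2·10⁻⁵ per vesicle (≈ 9·10⁻⁴ per 10-vesicle pool per ms; the
source also quotes 7.5·10⁻⁴, a ~20 % discrepancy we resolve in favour of
the curve).

**Vesicle pools.** Each neuron carries a readily releasable pool
(RRP, capacity 10), a recycling pool (ReP, 20) and a reserve pool
(RP, 170). Release is binomial: X ~ B(⌊RRP⌋, Pr). Pool transfer is forward
Euler at dt = 1 ms with per-vesicle rates: ReP→RRP priming at
R_max · Ca/(Ca + K_d) (R_max = 7.3·10⁻⁴ per ms, K_d = 2.3 μM — the
calcium-dependent priming step), the coupled backward rate
(τ_RRP→ReP = τ_ReP→RRP · RRP_full/ReP_full, detailed balance at full
occupancy), RP→ReP at 1/30 s⁻¹·ms scale (τ = 30 s) with its coupled
backward rate, and an external refill source (RP_full − RP)/τ with
τ = 50 s. Pools are continuous-valued, clamped to [0, capacity] after each
step; only release and the external refill change the total. R_max's
printed unit (s⁻¹) is inconsistent with the stated per-burst recycling-pool
consumption; the per-ms reading reproduces it and is the default
(`r_max_per_second` switches the interpretation).

**Topology.** Neurons sit uniformly on a 100×100 plate (hard boundaries —
a physical MEA, not a torus). Out-degrees come from a generalized Pareto
distribution (shape 0.25 by default) whose scale is solved so the clipped
mean equals connectivity_ratio · (n − 1); at the baseline 5 % and n = 800
this is ≈ 40 (the source also quotes "~45", an unresolved counting
convention). Targets are sampled without replacement with probability
proportional to a binomial pmf of the *distance rank* (defaults
n_trials = n − 1, p = 0.05), preferring local partners while keeping a
floor probability for long-range shortcuts. Connectivity is directed; the
realized ratio counts ordered pairs. Graph statistics (global clustering =
3·triangles / length-2 paths; Floyd–Warshall shortest paths; small-world
index against an Erdős–Rényi ensemble with matched node and edge counts)
are computed on the symmetrized unweighted graph.

## Manipulations

All manipulations are pure transforms of the configuration:

* **Asynchronous release** ("+100 %" ≙ strontium / DOC2B): both calcium
  clearance time constants × (1 + pct), excitatory and inhibitory alike.
* **Spontaneous release** (DOC2B mutant): the release curve gains a blended
  offset pct · Pr(rest) · w(Ca) with w(rest) = 1 and w → 0 at saturating
  calcium (w is the normalized complement of the curve's sigmoid), so Pr at
  rest scales by (1 + pct) while the evoked limb is unchanged. The closed
  form is this package's construction; the source only draws the curve.
* **Priming rate** (Munc13-1): R_max × factor; the backward rate follows
  through the coupling.
* **Gain sweeps** (EPSP ×, connectivity ratio) and **network scaling**
  (n × 10, or k = 10 independent presynaptic compartments per neuron with
  q/k so the expected drive per AP is unchanged).

## Burst analytics

Active units are those with whole-recording rate > 0.02 s⁻¹ (strict). The
pooled spike train of active units is split at gaps > 100 ms; an epoch is a
network burst if it contains ≥ 10 spikes and the smoothed network rate
(25-ms bins, 3-bin boxcar — both config-exposed; the source does not print
them) within it reaches 5 % of the recording-wide maximum. Initiation and
termination are the epoch's first and last spikes. Bursts with strictly
> 50 % of active units participating are "full", otherwise "aborted".
Synchronization is the mean pairwise Pearson correlation of binned
in-burst spike counts (unit count vectors are z-scored first;
normalization against a designated baseline run is supported). The
spike-count floor exists because an isolated spike in an otherwise
burst-free record would trivially pass a threshold defined relative to the
recording's own maximum.

Pool-dynamics analyses align bursts at initiation and average state traces
over participating neurons: occupancy curves, the fraction of participants
below an occupancy threshold at termination, cumulative per-neuron release
over the first 300 ms, and per-burst recycling-pool consumption.

## Operating-point calibration (important)

Two constants are calibrated rather than copied, and one published
constant's unit is re-read; everything else is the published value.

1. **Synaptic weight scale.** With the published per-vesicle EPSP
   (3.16 mV) and the raw lognormal weight scale (mean ≈ 0.71), the network
   is *mean-field silent*: after one burst from the fully-primed initial
   state it settles into a subcritical rest (RRP equilibrium ≈ 2.4
   vesicles) and never re-ignites — minis of ~2 mV against a 40-mV
   threshold cannot produce the documented recurrent bursting under any
   reading we found (heavier in-degree tails, alternative basal-Pr
   calibration, alternative priming units, alternative distance kernels
   were all tested and rejected). The lognormal parameters are therefore
   treated as fixing the *shape* of connection heterogeneity, and the
   overall scale (`weight_mean`, the pre-truncation mean; default 5.0,
   realized mean ≈ 3.2 after the A_max cut) is the model's single
   operating-point calibration, chosen once so the baseline reproduces the
   documented regime: recurrent network bursts (~10 per minute), durations
   of several hundred ms, majority participation with a full/aborted mix,
   ongoing inter-burst activity, and ≥ 70 % of participants below 2 RRP
   vesicles at termination.
2. **Fast-transient convention** (above): one-step action at τ_fast = dt.

### Known limitations at this operating point

* The recycling-pool *magnitudes* undershoot the reference values: per-burst
  ReP consumption is capped by the priming outflow
  (ReP · R_max · MM(Ca) · duration ≈ 4 vesicles gross for a 500-ms burst),
  so the fractions of neurons below 8 of 20 ReP vesicles at termination
  (reference ~7 % baseline, ~46 % slowed clearance) and the ~2-vesicle
  extra early-burst release are reproduced in *direction* but not in
  magnitude. Raising the priming rate ~10× recovers those magnitudes but
  erases the priming-manipulation responses (ceiling effect), which we
  consider the more load-bearing prediction; the trade-off appears
  intrinsic to the published constants.
* Bursting collapses below ~1× EPSP gain (the documented robustness region
  extends to 0.5×); above ~2× activity becomes near-continuous.
* The generator emulates spontaneous culture activity only: no sensory
  drive, no plasticity, no conduction delays, no electrode sampling or
  noise — detection operates on the true spike trains, so passing analytics
  tests says nothing about spike-sorting artifacts in real MEA data.

## Numerical and design choices

* dt = 1 ms fixed; voltage and slow calcium use exact exponential decay;
  pools use forward Euler (stable at these rates; capacity clamps guard the
  overshoot).
* One master seed; numpy PCG64 with `SeedSequence` spawning (topology and
  simulation substreams); the engine is fully vectorized, so results are
  independent of neuron iteration order and bitwise reproducible per seed.
* Initial conditions: V = 0 (rest), calcium at rest, pools full; the first
  60 s are excluded from all statistics as a non-stationary transient
  (`warmup_ms`).
* Distance-rank ties break by neuron index; degree rounding to integers in
  [1, n − 1]; the GPD scale is solved with Brent's method on the clipped
  mean.
* Synchronous vs asynchronous windows in the single-neuron protocol:
  synchronous = the AP step (time-locked at 1-ms resolution), asynchronous
  = the remainder of the 50-ms window; both are arguments.
* Analysis problem sizes: the standing test battery uses 2-minute runs
  (5 seeds × 4 conditions); the acceptance computations use 10 simulated
  minutes per run, 1 matched seed for the pool comparisons and 3 seeds for
  the priming comparison; topology metrics use 5 topology seeds × 20
  Erdős–Rényi references.
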