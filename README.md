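# presynet

A spiking-network simulator in which **network activity is generated by the
presynaptic release machinery** rather than by injected current: leaky
integrate-and-fire (LIF) neurons whose output comes from calcium-dependent,
stochastic vesicle release out of a three-pool vesicle system. The package
targets the spontaneous activity of cortical cultures on microelectrode
arrays (MEAs) — recurrent network-wide bursts separated by quiescence — and
the question of how single-synapse changes (more asynchronous release, more
spontaneous release, faster vesicle priming) reshape that network activity.

## Who it is for

Computational neuroscientists studying network bursts, synchronization and
short-term synaptic dynamics in vitro; experimentalists who want an
in-silico counterpart to strontium / DOC2B / Munc13-1-type manipulations.

## The model

Each of N = 800 neurons (30 % inhibitory) on a 2D plate, wired with a
small-world / scale-free directed topology (heavy-tailed out-degrees,
distance-ranked target selection, lognormal weights A_ij truncated at
A_max = 10), carries a LIF membrane and one pooled presynaptic compartment:

* membrane: τ_m dV/dt = −V + V_syn, threshold θ, reset V_hyp, absolute
  refractory period τ_arp = 3 ms;
* synaptic input: V_syn(i) = Σ_j A_ij · x_j · q with q = 3.16 mV per
  released vesicle and a one-step (1 ms) synaptic delay;
* calcium: [Ca]_tot = [Ca]_fast + [Ca]_slow + [Ca]_rest; an AP sets the
  fast pool to 13.6 μM for one step and adds 0.5 μM to the slow pool
  (τ_slow = 31 ms, ceiling 1.36 μM);
* release probability per vesicle:
  Pr(Ca) = α / (1 + e^(−β·log₁₀Ca + γ)) + δ, ceiling 0.15 at maximal
  calcium, ~9·10⁻⁵ at rest (spontaneous release);
* vesicle pools: RRP (10) ⇄ ReP (20) ⇄ RP (170), with calcium-dependent
  Michaelis–Menten priming ReP→RRP (rate R_max·Ca/(Ca+K_d)) and binomial
  release X ~ B(⌊RRP⌋, Pr).

Spontaneous vesicle release at resting calcium keeps the network alive;
coincident miniature PSPs occasionally ignite a cascade; the burst
terminates when most participants' RRPs run empty, and the
calcium-dependent priming step paces recovery — and hence burst frequency.
See `docs/methods.md` for the full model, the operating-point calibration
(one free weight-scale constant) and known limitations.

## Worked example

```python
from presynet import (SimulationConfig, simulate, detect_bursts,
                      burst_statistics)

config = SimulationConfig(duration_ms=120_000, warmup_ms=30_000, seed=1)
result = simulate(config)
spikes = result.spikes.restricted(config.warmup_ms)   # drop the transient
stats = burst_statistics(spikes, detect_bursts(spikes))
```

This is `examples/01_simulate_baseline.py`; running it prints:

```
34446 spikes from 800 neurons over 90 s
bursts/min          : 8.7
mean duration (ms)  : 308
mean spikes/burst   : 2608
participation ratio : 0.97
full-burst fraction : 1.00
inter-burst rate    : 6.3 spikes/s
```

i.e. the network oscillates at ~9 bursts per minute; each burst lasts a few
hundred milliseconds, recruits nearly every active neuron ("full" bursts),
and a nonzero spontaneous background persists between bursts. The
`examples/` directory has one short script per capability: baseline
simulation, topology metrics, single-neuron release histograms,
manipulation experiments, and the planted-burst fixture generator. A thin
CLI mirrors the library:

```bash
presynet simulate --seed 1 --duration-min 2 --out run/ \
                  --manipulation async=+100%
presynet analyze --spikes run/spikes.csv --out analysis/
presynet topology-stats --seed 1 --er-reps 20 --out stats.json
```

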