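"""Network simulation engine.

Advances the whole network on a fixed 1-ms grid.  Per step and per neuron,
in order: (1) synaptic input from the *previous* step's vesicle releases
(one-step synaptic delay), (2) leaky integrate-and-fire voltage update with
absolute refractoriness, (3) calcium update (AP-triggered influx plus
exponential clearance), (4) calcium-dependent release probability,
(5) binomial vesicle release, (6) vesicle-pool bookkeeping.

Voltages are tracked relative to rest: threshold at theta - V_rest (40 mV
with defaults) and post-spike reset to V_hyp - V_rest (-7 mV).  Inputs
arriving during the refractory period are discarded.

Releases from all of a neuron's synapses are pooled into a single output
x_j that is broadcast to every postsynaptic partner scaled by the signed
weight A_ij and the per-vesicle PSP q.  With k > 1 independent compartments
per neuron, q is divided by k so the expected postsynaptic drive per AP is
unchanged.

Everything is vectorized over neurons; a fixed master seed gives bitwise
reproducible spike records.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .config import SimulationConfig
from .synapse import ReleaseParams, release_probability, priming_rate
from .topology import NetworkTopology, generate_topology

__all__ = [
    "SpikeRecord",
    "StateTrace",
    "SimulationResult",
    "synaptic_input",
    "step_voltage",
    "simulate",
    "single_neuron_release_histogram",
]


class SimulationDiverged(RuntimeError):
    """Raised when non-finite state is detected during integration."""


@dataclass
class SpikeRecord:
    """All spikes of a run: integer times (ms) and unit ids, time-sorted."""

    times: np.ndarray        # int64, sorted by (time, unit)
    units: np.ndarray        # int64
    n_neurons: int
    duration_ms: int

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def spike_times(self, unit: int) -> np.ndarray:
        return self.times[self.units == unit]

    def per_unit(self) -> list[np.ndarray]:
        order = np.lexsort((self.times, self.units))
        units = self.units[order]
        times = self.times[order]
        bounds = np.searchsorted(units, np.arange(self.n_neurons + 1))
        return [times[bounds[i]:bounds[i + 1]] for i in range(self.n_neurons)]

    def restricted(self, t_from: int = 0, t_to: int | None = None) -> "SpikeRecord":
        """Sub-record on [t_from, t_to), re-origined at t_from."""
        t_to = self.duration_ms if t_to is None else t_to
        keep = (self.times >= t_from) & (self.times < t_to)
        return SpikeRecord(times=self.times[keep] - t_from,
                           units=self.units[keep],
                           n_neurons=self.n_neurons,
                           duration_ms=t_to - t_from)


@dataclass
class StateTrace:
    """Sampled per-neuron state time series on the dt grid.

    ``arrays[name]`` has shape (n_samples, n_recorded_neurons); sample i was
    taken at time ``start_ms + i * stride_ms``.
    """

    arrays: dict[str, np.ndarray]
    start_ms: int
    stride_ms: int
    neurons: np.ndarray      # recorded neuron ids

    @property
    def n_samples(self) -> int:
        return next(iter(self.arrays.values())).shape[0] if self.arrays else 0

    def index_of(self, t_ms: float) -> int:
        """Index of the sample at (or immediately before) time t_ms."""
        idx = int((t_ms - self.start_ms) // self.stride_ms)
        if idx < 0 or idx >= self.n_samples:
            raise IndexError(f"time {t_ms} ms outside trace coverage")
        return idx


@dataclass
class SimulationResult:
    spikes: SpikeRecord
    trace: StateTrace | None
    config: SimulationConfig
    topology: NetworkTopology
    seed: int


def synaptic_input(releases_prev: np.ndarray, topology: NetworkTopology,
                   q: float) -> np.ndarray:
    """V_syn(i) = sum_j A_ij * x_j * q for previous-step releases x."""
    releases_prev = np.asarray(releases_prev, dtype=float)
    if np.any(releases_prev < 0):
        raise ValueError("release counts must be nonnegative")
    return q * (topology.adjacency @ releases_prev)


def step_voltage(v: np.ndarray, refractory: np.ndarray, v_syn: np.ndarray,
                 decay: float, theta_rel: float, v_hyp_rel: float,
                 tau_arp: int) -> np.ndarray:
    """One LIF step, in place.  Returns the boolean spike mask.

    Refractory neurons hold their reset voltage and discard input; others
    decay exponentially and add this step's synaptic input.  Crossing the
    threshold emits a spike, resets the voltage and starts the refractory
    counter.
    """
    in_refr = refractory > 0
    np.subtract(refractory, 1, out=refractory, where=in_refr)
    integrated = v * decay + v_syn
    np.copyto(v, integrated, where=~in_refr)
    spiked = (~in_refr) & (v >= theta_rel)
    v[spiked] = v_hyp_rel
    refractory[spiked] = tau_arp
    return spiked


def simulate(config: SimulationConfig, topology: NetworkTopology | None = None,
             seed: int | None = None) -> SimulationResult:
    """Run the full network for ``config.duration_ms`` simulated milliseconds.

    The master seed (argument overrides ``config.seed``) drives two
    independent substreams, one for topology generation and one for the
    stochastic release draws, so the same wiring can be reused across
    manipulated conditions by passing ``topology`` explicitly.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    topo_ss, sim_ss = ss.spawn(2)
    if topology is None:
        topology = generate_topology(config, np.random.default_rng(topo_ss))
    rng = np.random.default_rng(sim_ss)

    n = config.n_neurons
    if topology.n_neurons != n:
        raise ValueError("topology size does not match config.n_neurons")
    k = config.synapses_per_neuron
    params = ReleaseParams.from_config(config)
    q = config.epsp_mv / k
    steps = int(round(config.duration_ms / config.dt_ms))
    dt = config.dt_ms

    adjacency = topology.adjacency.tocsr()
    decay_v = float(np.exp(-dt / config.tau_m))
    # The fast-calcium transient is a sub-grid event: at the baseline
    # tau_fast = dt = 1 ms the AP-triggered fast calcium acts for exactly one
    # step (release probability 0.15 -> ~1.5 vesicles per AP, the calibration
    # the per-vesicle EPSP q is built on).  Slower clearance (the asynchronous
    # manipulation) prolongs it via the linear-decay factor (1 - dt/tau).
    decay_f = max(0.0, 1.0 - dt / config.tau_ca_fast)
    decay_s = float(np.exp(-dt / config.tau_ca_slow))
    theta_rel = config.theta_rel
    v_hyp_rel = config.v_hyp_rel
    tau_arp = int(round(config.tau_arp))

    # state (pools have a compartment axis; k = 1 keeps it size one)
    v = np.zeros(n)
    refractory = np.zeros(n, dtype=np.int64)
    ca_fast = np.zeros(n)
    ca_slow = np.zeros(n)
    rrp = np.full((n, k), params.rrp_full)
    rep = np.full((n, k), params.rep_full)
    rp = np.full((n, k), params.rp_full)
    x_prev = np.zeros(n)

    # pool transfer rate constants (see synapse.step_pools); the calcium-
    # dependent priming rate is recomputed each step
    k_rp_rep = dt / params.tau_rep_replenish
    k_rep_rp = k_rp_rep * params.rp_full / params.rep_full
    k_refill = dt / params.tau_rp_replenish
    back_ratio = params.rep_full / params.rrp_full

    spike_t: list[np.ndarray] = []
    spike_u: list[np.ndarray] = []

    trace = None
    trace_arrays: dict[str, np.ndarray] = {}
    if config.record_trace:
        rec_ids = (np.arange(n) if config.trace_neurons is None
                   else np.asarray(config.trace_neurons, dtype=int))
        n_rec_steps = max(0, (steps - config.trace_start_ms
                              + config.trace_stride - 1) // config.trace_stride)
        dtype = np.dtype(config.trace_dtype)
        for name in config.trace_vars:
            dt_name = np.uint8 if name == "released" else dtype
            trace_arrays[name] = np.zeros((n_rec_steps, rec_ids.size),
                                          dtype=dt_name)
        trace = StateTrace(arrays=trace_arrays, start_ms=config.trace_start_ms,
                           stride_ms=config.trace_stride, neurons=rec_ids)

    v_syn = np.zeros(n)
    for t in range(steps):
        # (1) synaptic input from previous-step releases
        if x_prev.any():
            v_syn = q * (adjacency @ x_prev)
        else:
            v_syn.fill(0.0)

        # (2) voltage and spiking
        spiked = step_voltage(v, refractory, v_syn, decay_v, theta_rel,
                              v_hyp_rel, tau_arp)

        # (3) calcium: exact exponential clearance, then AP-driven influx
        ca_fast *= decay_f
        ca_slow *= decay_s
        if spiked.any():
            ca_fast[spiked] = params.ca_fast_max
            ca_slow[spiked] = np.minimum(
                ca_slow[spiked] + params.ap_influx_slow, params.ca_slow_max)
            idx = np.nonzero(spiked)[0]
            spike_t.append(np.full(idx.size, t, dtype=np.int64))
            spike_u.append(idx)

        # (4) release probability from the post-update calcium
        ca_tot = ca_fast + ca_slow + params.ca_rest
        pr = release_probability(ca_tot, params)

        # (5) binomial release per compartment
        trials = rrp.astype(np.int64)  # floor of nonnegative pool
        x = rng.binomial(trials, pr[:, None])
        x_total = x.sum(axis=1).astype(float)

        # (6) vesicle-pool update (forward Euler, dt = 1 ms)
        k_f = priming_rate(ca_tot, params)[:, None] * dt
        f_prime = rep * k_f
        f_demote = rrp * (k_f * back_ratio)
        f_refill_rep = rp * k_rp_rep
        f_return = rep * k_rep_rp
        f_source = (params.rp_full - rp) * k_refill
        rrp += f_prime - f_demote - x
        rep += f_demote - f_prime + f_refill_rep - f_return
        rp += f_source + f_return - f_refill_rep
        np.clip(rrp, 0.0, params.rrp_full, out=rrp)
        np.clip(rep, 0.0, params.rep_full, out=rep)
        np.clip(rp, 0.0, params.rp_full, out=rp)

        x_prev = x_total

        if trace is not None and t >= config.trace_start_ms \
                and (t - config.trace_start_ms) % config.trace_stride == 0:
            i = (t - config.trace_start_ms) // config.trace_stride
            ids = trace.neurons
            for name, arr in trace_arrays.items():
                if name == "rrp":
                    arr[i] = rrp[ids].sum(axis=1)
                elif name == "rep":
                    arr[i] = rep[ids].sum(axis=1)
                elif name == "rp":
                    arr[i] = rp[ids].sum(axis=1)
                elif name == "released":
                    arr[i] = x[ids].sum(axis=1)
                elif name == "ca_total":
                    arr[i] = ca_tot[ids]
                elif name == "v":
                    arr[i] = v[ids]
                else:
                    raise ValueError(f"unknown trace variable {name!r}")

        if t % 10_000 == 0 and not np.isfinite(v).all():
            raise SimulationDiverged(f"non-finite membrane voltage at t={t} ms")

    if not np.isfinite(v).all():
        raise SimulationDiverged("non-finite membrane voltage at end of run")

    times = (np.concatenate(spike_t) if spike_t
             else np.array([], dtype=np.int64))
    units = (np.concatenate(spike_u) if spike_u
             else np.array([], dtype=np.int64))
    spikes = SpikeRecord(times=times, units=units, n_neurons=n,
                         duration_ms=config.duration_ms)
    return SimulationResult(spikes=spikes, trace=trace, config=config,
                            topology=topology, seed=seed)


def single_neuron_release_histogram(
        config: SimulationConfig, n_trials: int, window_ms: int = 50,
        seed: int = 0, sync_window_ms: float = 1.0,
        force_pr_zero: bool = False):
    """Release raster of an isolated neuron after a forced AP at t = 0.

    Starting from rest (full pools, resting calcium), an AP is forced at
    t = 0 of every trial and the compartment is stepped for ``window_ms``.
    Returns ``(per_ms_mean, async_sync_ratio)`` where ``per_ms_mean[t]`` is
    the mean number of vesicles released in millisecond t, and the ratio
    compares release inside the asynchronous window [sync_window, window] to
    the synchronous window [0, sync_window).  Synchronous release is the
    release time-locked to the AP, which on the 1-ms grid is the AP step
    itself, hence the default 1-ms synchronous window.
    """
    import warnings
    if n_trials < 100:
        warnings.warn("n_trials < 100 gives a noisy release histogram",
                      stacklevel=2)
    params = ReleaseParams.from_config(config)
    rng = np.random.default_rng(seed)
    dt = config.dt_ms
    decay_f = max(0.0, 1.0 - dt / params.tau_ca_fast)  # one-step fast transient
    decay_s = np.exp(-dt / params.tau_ca_slow)
    back_ratio = params.rep_full / params.rrp_full
    k_rp_rep = dt / params.tau_rep_replenish
    k_rep_rp = k_rp_rep * params.rp_full / params.rep_full
    k_refill = dt / params.tau_rp_replenish

    ca_fast = np.zeros(n_trials)
    ca_slow = np.zeros(n_trials)
    rrp = np.full(n_trials, params.rrp_full)
    rep = np.full(n_trials, params.rep_full)
    rp = np.full(n_trials, params.rp_full)
    counts = np.zeros(window_ms + 1)

    for t in range(window_ms + 1):
        ca_fast *= decay_f
        ca_slow *= decay_s
        if t == 0:  # the forced AP
            ca_fast[:] = params.ca_fast_max
            ca_slow[:] = np.minimum(ca_slow + params.ap_influx_slow,
                                    params.ca_slow_max)
        ca_tot = ca_fast + ca_slow + params.ca_rest
        pr = np.zeros(n_trials) if force_pr_zero \
            else release_probability(ca_tot, params)
        x = rng.binomial(rrp.astype(np.int64), pr)
        counts[t] = x.mean()
        k_f = priming_rate(ca_tot, params) * dt
        f_prime = rep * k_f
        f_demote = rrp * k_f * back_ratio
        f_refill_rep = rp * k_rp_rep
        f_return = rep * k_rep_rp
        f_source = (params.rp_full - rp) * k_refill
        rrp = np.clip(rrp + f_prime - f_demote - x, 0.0, params.rrp_full)
        rep = np.clip(rep + f_demote - f_prime + f_refill_rep - f_return,
                      0.0, params.rep_full)
        rp = np.clip(rp + f_source + f_return - f_refill_rep, 0.0,
                     params.rp_full)

    sync = counts[:int(sync_window_ms)].sum()
    asyn = counts[int(sync_window_ms):].sum()
    ratio = asyn / sync if sync > 0 else np.inf if asyn > 0 else np.nan
    return counts, ratio
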