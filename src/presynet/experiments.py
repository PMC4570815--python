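"""Experiment driver: baseline-vs-manipulation comparisons.

Each named experiment runs the baseline configuration and one or more
manipulated conditions over a list of seeds (topology matched within a seed),
applies the burst analytics, and returns a tidy comparison table plus the
derived headline quantities.  These are the in-silico counterparts of the
strontium / DOC2B / Munc13-1 manipulation experiments the model emulates.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import burst as B
from .config import SimulationConfig
from .engine import SimulationResult, simulate
from .manipulations import (apply_async, apply_gain_sweep, apply_priming,
                            apply_scale, apply_spontaneous)
from .topology import generate_topology

__all__ = ["ExperimentReport", "run_condition", "condition_metrics",
           "run_experiment", "EXPERIMENTS"]

# trace settings used whenever pool dynamics are analyzed
_TRACE_KW = dict(record_trace=True, trace_vars=("rrp", "rep", "released"),
                 trace_dtype="float16")


@dataclass
class ConditionMetrics:
    """Burst statistics plus (optional) pool-dynamics measures for one run."""

    stats: B.BurstStatistics
    rrp_below2_at_term: float | None = None
    rep_below8_at_term: float | None = None
    cumulative_release_300ms: float | None = None
    rep_consumption: float | None = None

    def as_row(self) -> dict:
        row = {
            "bursts_per_min": self.stats.bursts_per_min,
            "mean_duration_ms": self.stats.mean_duration_ms,
            "mean_spikes_per_burst": self.stats.mean_spikes_per_burst,
            "mean_peak_rate": self.stats.mean_peak_rate,
            "global_spike_rate": self.stats.global_spike_rate,
            "participation_ratio": self.stats.participation_ratio,
            "full_burst_fraction": self.stats.full_burst_fraction,
            "mean_time_to_peak_ms": self.stats.mean_time_to_peak_ms,
            "n_bursts": self.stats.n_bursts,
        }
        for key in ("rrp_below2_at_term", "rep_below8_at_term",
                    "cumulative_release_300ms", "rep_consumption"):
            value = getattr(self, key)
            if value is not None:
                row[key] = value
        return row


@dataclass
class ExperimentReport:
    name: str
    table: pd.DataFrame              # one row per (condition, seed)
    comparison: pd.DataFrame         # percent / absolute change vs baseline

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out_dir / f"{self.name}_conditions.csv", index=False)
        self.comparison.to_csv(out_dir / f"{self.name}_comparison.csv",
                               index=False)


def run_condition(config: SimulationConfig, seed: int,
                  topology=None) -> SimulationResult:
    return simulate(config, topology=topology, seed=seed)


def condition_metrics(result: SimulationResult,
                      with_pools: bool = False) -> ConditionMetrics:
    """Analyze one run: detect bursts post-warmup, compute statistics."""
    config = result.config
    sp = result.spikes.restricted(config.warmup_ms)
    bursts = B.detect_bursts(sp)
    stats = B.burst_statistics(sp, bursts)
    metrics = ConditionMetrics(stats=stats)
    if with_pools and result.trace is not None and bursts:
        # burst times are relative to warmup; traces are in absolute time
        for b in bursts:
            b.t_start += config.warmup_ms
            b.t_end += config.warmup_ms
            b.t_peak += config.warmup_ms
        tr = result.trace
        metrics.rrp_below2_at_term = B.fraction_below_at_termination(
            tr, bursts, "rrp", 2.0)
        metrics.rep_below8_at_term = B.fraction_below_at_termination(
            tr, bursts, "rep", 8.0)
        metrics.cumulative_release_300ms = B.cumulative_release_per_neuron(
            tr, bursts, 300)
        metrics.rep_consumption = B.pool_consumption_per_burst(
            tr, bursts, "rep")
    return metrics


# --------------------------------------------------------------------------
# headline quantity computations (used by the acceptance script and tests)
# --------------------------------------------------------------------------

def release_probability_ceiling() -> float:
    """Per-vesicle release probability at the maximal attainable calcium
    (fast ceiling + slow ceiling + rest)."""
    from .synapse import ReleaseParams, release_probability
    p = ReleaseParams()
    return float(release_probability(p.ca_total_max, p))


def topology_small_world_metrics(seeds, n_reference: int = 20,
                                 config: SimulationConfig | None = None):
    """Small-world metrics of freshly generated baseline topologies,
    one per seed, each normalized against its own E-R ensemble."""
    from .topology import small_world_index

    config = SimulationConfig() if config is None else config
    out = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        topo = generate_topology(config, rng)
        out.append(small_world_index(topo, n_reference=n_reference, rng=rng))
    return out


def pool_depletion_comparison(seeds, duration_ms: int = 600_000,
                              warmup_ms: int = 60_000,
                              clearance_factor: float = 2.0,
                              base: SimulationConfig | None = None) -> dict:
    """Baseline vs slowed-clearance pool dynamics, seed- and topology-matched.

    Returns per-condition means of the burst-termination depletion measures
    plus the async-vs-baseline differences in cumulative early-burst release
    and recycling-pool consumption.
    """
    base = SimulationConfig() if base is None else base
    base = base.replace(duration_ms=duration_ms, warmup_ms=warmup_ms,
                        **_TRACE_KW, trace_start_ms=warmup_ms)
    asyn = apply_async(base, clearance_factor - 1.0)
    rows = {"baseline": [], "async": []}
    for seed in seeds:
        ss = np.random.SeedSequence(seed)
        topo_ss, _ = ss.spawn(2)
        topo = generate_topology(base, np.random.default_rng(topo_ss))
        for label, cfg in (("baseline", base), ("async", asyn)):
            result = run_condition(cfg, seed, topology=topo)
            rows[label].append(condition_metrics(result, with_pools=True))
            del result

    def mean(label, attr):
        vals = [getattr(m, attr) for m in rows[label]
                if getattr(m, attr) is not None]
        return float(np.mean(vals)) if vals else np.nan

    return {
        "baseline_rrp_below2_pct": 100 * mean("baseline", "rrp_below2_at_term"),
        "baseline_rep_below8_pct": 100 * mean("baseline", "rep_below8_at_term"),
        "async_rep_below8_pct": 100 * mean("async", "rep_below8_at_term"),
        "extra_release_300ms": (mean("async", "cumulative_release_300ms")
                                - mean("baseline", "cumulative_release_300ms")),
        "extra_rep_consumption": (mean("async", "rep_consumption")
                                  - mean("baseline", "rep_consumption")),
        "baseline_bursts_per_min": float(np.mean(
            [m.stats.bursts_per_min for m in rows["baseline"]])),
    }


def priming_comparison(seeds, duration_ms: int = 600_000,
                       warmup_ms: int = 60_000, factor: float = 1.5,
                       base: SimulationConfig | None = None) -> dict:
    """Baseline vs scaled-priming burst statistics over matched seeds."""
    base = SimulationConfig() if base is None else base
    base = base.replace(duration_ms=duration_ms, warmup_ms=warmup_ms)
    manip = apply_priming(base, factor)
    peaks = {"baseline": [], "priming": []}
    freqs = {"baseline": [], "priming": []}
    for seed in seeds:
        ss = np.random.SeedSequence(seed)
        topo_ss, _ = ss.spawn(2)
        topo = generate_topology(base, np.random.default_rng(topo_ss))
        for label, cfg in (("baseline", base), ("priming", manip)):
            result = run_condition(cfg, seed, topology=topo)
            m = condition_metrics(result)
            peaks[label].append(m.stats.mean_peak_rate)
            freqs[label].append(m.stats.bursts_per_min)
            del result
    peak_base = float(np.mean(peaks["baseline"]))
    peak_manip = float(np.mean(peaks["priming"]))
    return {
        "peak_rate_pct_change": 100.0 * (peak_manip - peak_base) / peak_base,
        "burst_freq_change_per_min": float(np.mean(freqs["priming"])
                                           - np.mean(freqs["baseline"])),
        "baseline_bursts_per_min": float(np.mean(freqs["baseline"])),
    }


def _conditions_for(name: str, base: SimulationConfig):
    if name == "fig2_async":
        return {"baseline": base, "async_+100%": apply_async(base, 1.0)}, False
    if name == "fig2_spont":
        return {"baseline": base, "spont_+100%": apply_spontaneous(base, 1.0)}, False
    if name == "fig3_pools":
        base = base.replace(**_TRACE_KW, trace_start_ms=base.warmup_ms)
        return {"baseline": base, "async_+100%": apply_async(base, 1.0)}, True
    if name == "fig4_priming":
        return {"baseline": base,
                "priming_x0.5": apply_priming(base, 0.5),
                "priming_x1.5": apply_priming(base, 1.5)}, False
    if name == "s4_sweep":
        grid = apply_gain_sweep(base, (0.5, 1.0, 2.0), (0.025, 0.05, 0.10))
        return {f"epsp_x{c.epsp_mv / base.epsp_mv:g}_conn_{c.connectivity_ratio:g}": c
                for c in grid}, False
    if name == "s5_scale":
        return {"baseline": base,
                "neurons_x10": apply_scale(base, 10.0),
                "synapses_x10": apply_scale(base, 1.0, 10)}, False
    raise ValueError(f"unknown experiment {name!r}")


EXPERIMENTS = ("fig2_async", "fig2_spont", "fig3_pools", "fig4_priming",
               "s4_sweep", "s5_scale")


def run_experiment(name: str, seeds, base: SimulationConfig | None = None,
                   out_dir: str | Path | None = None) -> ExperimentReport:
    """Run baseline + manipulated conditions over seeds and compare.

    Within each seed the baseline topology is reused for every condition
    that shares the baseline's network structure, so condition differences
    are not confounded by wiring realizations.
    """
    base = SimulationConfig() if base is None else base
    conditions, with_pools = _conditions_for(name, base)
    rows = []
    for seed in seeds:
        topo_cache: dict[tuple, object] = {}
        for label, cfg in conditions.items():
            topo_key = (cfg.n_neurons, cfg.connectivity_ratio)
            topo = topo_cache.get(topo_key)
            if topo is None:
                ss = np.random.SeedSequence(seed)
                topo_ss, _ = ss.spawn(2)
                topo = generate_topology(cfg, np.random.default_rng(topo_ss))
                topo_cache[topo_key] = topo
            result = run_condition(cfg, seed, topology=topo)
            metrics = condition_metrics(result, with_pools=with_pools)
            rows.append({"condition": label, "seed": seed,
                         **metrics.as_row()})
            del result
    table = pd.DataFrame(rows)

    numeric = [c for c in table.columns if c not in ("condition", "seed")]
    means = table.groupby("condition")[numeric].mean()
    comparison = means.copy()
    if "baseline" in means.index:
        baseline = means.loc["baseline"]
        for col in numeric:
            with np.errstate(divide="ignore", invalid="ignore"):
                comparison[f"{col}_pct_change"] = 100.0 * (
                    means[col] - baseline[col]) / baseline[col]
            comparison[f"{col}_abs_change"] = means[col] - baseline[col]
    comparison = comparison.reset_index()

    report = ExperimentReport(name=name, table=table, comparison=comparison)
    if out_dir is not None:
        report.save(out_dir)
    return report
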