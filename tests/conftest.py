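"""Shared fixtures.

Network simulations are expensive, so everything derived from a full run is
computed once per session and shared: a short baseline run, and a battery of
manipulated conditions over several seeds used by the directional (sign)
tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from presynet import (SimulationConfig, simulate, detect_bursts,
                      burst_statistics, generate_topology)
from presynet.manipulations import (apply_async, apply_priming,
                                    apply_spontaneous)

BATTERY_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_config():
    """2 simulated minutes, 30 s warmup: enough for ~15 bursts."""
    return SimulationConfig(duration_ms=120_000, warmup_ms=30_000, seed=7)


@pytest.fixture(scope="session")
def short_run(short_config):
    return simulate(short_config)


@pytest.fixture(scope="session")
def short_run_stats(short_config, short_run):
    spikes = short_run.spikes.restricted(short_config.warmup_ms)
    bursts = detect_bursts(spikes)
    return spikes, bursts, burst_statistics(spikes, bursts)


def _battery_stats(config):
    spikes = simulate(config).spikes.restricted(config.warmup_ms)
    return burst_statistics(spikes, detect_bursts(spikes))


@pytest.fixture(scope="session")
def condition_battery():
    """Burst statistics for baseline and manipulated conditions, 5 seeds.

    Returns {condition: [BurstStatistics per seed]} with topology matched to
    the baseline within each seed.
    """
    base = SimulationConfig(duration_ms=120_000, warmup_ms=30_000)
    conditions = {
        "baseline": base,
        "async+100%": apply_async(base, 1.0),
        "spont+100%": apply_spontaneous(base, 1.0),
        "priming_x0.5": apply_priming(base, 0.5),
    }
    out = {name: [] for name in conditions}
    for seed in BATTERY_SEEDS:
        ss = np.random.SeedSequence(seed)
        topo_ss, _ = ss.spawn(2)
        topo = generate_topology(base, np.random.default_rng(topo_ss))
        for name, cfg in conditions.items():
            res = simulate(cfg, topology=topo, seed=seed)
            spikes = res.spikes.restricted(cfg.warmup_ms)
            out[name].append(burst_statistics(spikes, detect_bursts(spikes)))
    return out
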