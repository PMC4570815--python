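"""Synthetic spike-train fixtures with planted network bursts.

The generator emits a homogeneous-Poisson background plus dense burst epochs
with configurable participation, so the burst-analysis pipeline can be
validated against known ground truth without running the simulator.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SpikeRecord

__all__ = ["BurstFixtureSpec", "generate_burst_fixture"]


@dataclass(frozen=True)
class BurstFixtureSpec:
    n_units: int = 50
    duration_ms: int = 60_000
    burst_times: tuple[float, ...] = (10_000.0, 30_000.0, 50_000.0)
    burst_duration_ms: float = 300.0
    in_burst_rate: float = 50.0       # spikes/s per participating unit
    participation: float = 0.8        # fraction of units active per burst
    background_rate: float = 0.1      # spikes/s per unit, whole record
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.duration_ms <= 0:
            raise ValueError("need n_units >= 1 and positive duration")
        if min(self.in_burst_rate, self.background_rate) < 0:
            raise ValueError("rates must be nonnegative")
        if not 0 <= self.participation <= 1:
            raise ValueError("participation must be in [0, 1]")
        starts = np.sort(np.asarray(self.burst_times, dtype=float))
        if np.any(np.diff(starts) < self.burst_duration_ms):
            raise ValueError("planted bursts overlap")
        if starts.size and (starts[0] < 0 or
                            starts[-1] + self.burst_duration_ms > self.duration_ms):
            raise ValueError("planted bursts fall outside the record")


def generate_burst_fixture(spec: BurstFixtureSpec,
                           rng: np.random.Generator | None = None):
    """Return ``(SpikeRecord, ground_truth)``.

    ``ground_truth`` is a DataFrame with one row per planted burst
    (t_start_ms, t_end_ms, n_participating) using the *planted* epoch bounds;
    participating units are guaranteed at least one spike inside the epoch.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    times, units = [], []

    # Poisson background for every unit
    if spec.background_rate > 0:
        lam = spec.background_rate * spec.duration_ms / 1000.0
        for u in range(spec.n_units):
            k = rng.poisson(lam)
            times.append(rng.uniform(0, spec.duration_ms, size=k))
            units.append(np.full(k, u))

    truth_rows = []
    n_part = int(round(spec.participation * spec.n_units))
    for t0 in spec.burst_times:
        members = rng.choice(spec.n_units, size=n_part, replace=False)
        lam = spec.in_burst_rate * spec.burst_duration_ms / 1000.0
        for u in members:
            k = max(int(rng.poisson(lam)), 1)   # guarantee participation
            times.append(t0 + rng.uniform(0, spec.burst_duration_ms, size=k))
            units.append(np.full(k, u))
        truth_rows.append({"t_start_ms": t0,
                           "t_end_ms": t0 + spec.burst_duration_ms,
                           "n_participating": n_part})

    if times:
        t = np.concatenate(times)
        u = np.concatenate(units).astype(np.int64)
    else:
        t = np.array([])
        u = np.array([], dtype=np.int64)
    t = np.floor(t).astype(np.int64)
    order = np.lexsort((u, t))
    record = SpikeRecord(times=t[order], units=u[order],
                         n_neurons=spec.n_units,
                         duration_ms=spec.duration_ms)
    truth = pd.DataFrame(truth_rows,
                         columns=["t_start_ms", "t_end_ms", "n_participating"])
    return record, truth
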