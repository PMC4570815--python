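"""Network-burst detection, classification and characterization.

A network burst is an epoch of dense, network-wide firing separated from its
neighbours by quiescence.  Detection follows the usual MEA convention:
candidate epochs are runs of pooled spikes (over active units) whose
consecutive inter-spike intervals stay below a maximum (100 ms by default);
an epoch counts as a burst when the smoothed network firing rate inside it
crosses a threshold fraction (5 %) of the recording-wide maximum rate.
Burst initiation/termination are the first/last spike of the epoch.

Bursts with strictly more than 50 % of units participating are "full",
otherwise "aborted".  Synchronization is the average pairwise Pearson
correlation of binned in-burst spike counts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import SpikeRecord, StateTrace

__all__ = [
    "NetworkBurst",
    "BurstStatistics",
    "network_rate",
    "active_units",
    "detect_bursts",
    "classify_bursts",
    "burst_profile",
    "synchronization",
    "burst_statistics",
    "pool_burst_average",
    "fraction_below_at_termination",
    "cumulative_release_per_neuron",
    "pool_consumption_per_burst",
    "raster_export",
]

DEFAULT_BIN_MS = 25
DEFAULT_SMOOTH_BINS = 3
DEFAULT_PEAK_THRESHOLD_FRAC = 0.05
DEFAULT_MAX_ISI_MS = 100.0
DEFAULT_MIN_BURST_SPIKES = 10
DEFAULT_MIN_RATE = 0.02  # s^-1; strict ">" activity criterion


@dataclass
class NetworkBurst:
    t_start: float            # ms, first spike
    t_end: float              # ms, last spike
    t_peak: float             # ms, max of the smoothed in-burst rate
    peak_rate: float          # spikes/s at the peak
    participants: np.ndarray  # unit ids with >= 1 spike inside the burst
    n_spikes: int
    label: str = "unclassified"   # full | aborted

    @property
    def n_participating(self) -> int:
        return int(self.participants.size)

    @property
    def duration_ms(self) -> float:
        return self.t_end - self.t_start

    @property
    def time_to_peak_ms(self) -> float:
        return self.t_peak - self.t_start


@dataclass
class BurstStatistics:
    bursts_per_min: float
    mean_duration_ms: float
    mean_spikes_per_burst: float
    mean_peak_rate: float
    global_spike_rate: float      # spikes/s over all units, whole record
    participation_ratio: float    # mean fraction of active units per burst
    full_burst_fraction: float
    mean_time_to_peak_ms: float
    interburst_rate: float        # spikes/s outside bursts
    n_bursts: int


def network_rate(spikes: SpikeRecord, bin_ms: int = DEFAULT_BIN_MS,
                 smooth_bins: int = DEFAULT_SMOOTH_BINS,
                 units: np.ndarray | None = None):
    """Smoothed population firing rate (spikes/s summed over units).

    Returns ``(bin_start_times_ms, rate)``.  ``units`` restricts the count to
    a subset (e.g. the active units).
    """
    if bin_ms < 1:
        raise ValueError("bin_ms must be >= 1")
    n_bins = int(np.ceil(spikes.duration_ms / bin_ms))
    times = spikes.times
    if units is not None:
        mask = np.isin(spikes.units, units)
        times = times[mask]
    counts = np.bincount(times // bin_ms, minlength=n_bins)[:n_bins]
    rate = counts * (1000.0 / bin_ms)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        rate = np.convolve(rate, kernel, mode="same")
    t = np.arange(n_bins) * bin_ms
    return t, rate


def active_units(spikes: SpikeRecord,
                 min_rate: float = DEFAULT_MIN_RATE) -> np.ndarray:
    """Units whose whole-recording mean rate strictly exceeds min_rate (s^-1)."""
    if spikes.duration_ms <= 0:
        raise ValueError("record has nonpositive duration")
    counts = np.bincount(spikes.units, minlength=spikes.n_neurons)
    rates = counts / (spikes.duration_ms / 1000.0)
    return np.nonzero(rates > min_rate)[0]


def detect_bursts(spikes: SpikeRecord,
                  peak_threshold_frac: float = DEFAULT_PEAK_THRESHOLD_FRAC,
                  max_isi_ms: float = DEFAULT_MAX_ISI_MS,
                  bin_ms: int = DEFAULT_BIN_MS,
                  smooth_bins: int = DEFAULT_SMOOTH_BINS,
                  min_rate: float = DEFAULT_MIN_RATE,
                  min_spikes: int = DEFAULT_MIN_BURST_SPIKES) -> list[NetworkBurst]:
    """Detect network bursts on the pooled spike train of active units.

    The pooled train is split into epochs at gaps exceeding ``max_isi_ms``;
    an epoch is a burst when it holds at least ``min_spikes`` spikes and the
    smoothed network rate within it reaches ``peak_threshold_frac`` times
    the recording-wide maximum smoothed rate.  The spike-count floor keeps
    isolated spikes in otherwise burst-free records from qualifying when
    they themselves set the recording maximum.  Overlap merging is implicit
    in the gap rule.
    """
    act = active_units(spikes, min_rate)
    if act.size == 0:
        return []
    mask = np.isin(spikes.units, act)
    times = spikes.times[mask]
    units = spikes.units[mask]
    order = np.argsort(times, kind="stable")
    times = times[order]
    units = units[order]
    if times.size == 0:
        return []

    t_axis, rate = network_rate(spikes, bin_ms, smooth_bins, units=act)
    max_rate = rate.max()
    if max_rate <= 0:
        return []
    threshold = peak_threshold_frac * max_rate

    gap_breaks = np.nonzero(np.diff(times) > max_isi_ms)[0]
    starts = np.concatenate([[0], gap_breaks + 1])
    ends = np.concatenate([gap_breaks, [times.size - 1]])

    bursts: list[NetworkBurst] = []
    for s, e in zip(starts, ends):
        if e - s + 1 < min_spikes:
            continue
        t0, t1 = float(times[s]), float(times[e])
        b0 = int(t0 // bin_ms)
        b1 = int(t1 // bin_ms) + 1
        segment = rate[b0:b1]
        if segment.size == 0 or segment.max() < threshold:
            continue
        peak_idx = b0 + int(np.argmax(segment))
        t_peak = float(np.clip(t_axis[peak_idx] + bin_ms / 2.0, t0, t1))
        bursts.append(NetworkBurst(
            t_start=t0, t_end=t1, t_peak=t_peak,
            peak_rate=float(segment.max()),
            participants=np.unique(units[s:e + 1]),
            n_spikes=int(e - s + 1)))
    return bursts


def classify_bursts(bursts: list[NetworkBurst], n_units: int) -> list[NetworkBurst]:
    """Label bursts full (> 50 % of units participate, strictly) or aborted."""
    if n_units <= 0:
        raise ValueError("n_units must be positive")
    for b in bursts:
        b.label = "full" if b.n_participating / n_units > 0.5 else "aborted"
    return bursts


def burst_profile(spikes: SpikeRecord, bursts: list[NetworkBurst],
                  window_ms: int = 1000, bin_ms: int = DEFAULT_BIN_MS,
                  units: np.ndarray | None = None):
    """Mean network rate aligned at burst initiation.

    Returns ``(time_in_burst_ms, mean_rate, time_to_peak_ms_per_burst)``.
    Bins beyond a burst's end are zero-padded.
    """
    if not bursts:
        raise ValueError("need at least one burst")
    times = spikes.times
    if units is not None:
        times = times[np.isin(spikes.units, units)]
    n_bins = window_ms // bin_ms
    profiles = np.zeros((len(bursts), n_bins))
    for i, b in enumerate(bursts):
        rel = times[(times >= b.t_start) & (times < b.t_start + window_ms)] - b.t_start
        profiles[i] = np.bincount((rel // bin_ms).astype(int),
                                  minlength=n_bins)[:n_bins] * (1000.0 / bin_ms)
    ttp = np.array([b.time_to_peak_ms for b in bursts])
    t = np.arange(n_bins) * bin_ms
    return t, profiles.mean(axis=0), ttp


@dataclass
class SynchronizationResult:
    overall: float                 # mean pairwise correlation, all in-burst bins
    profile: np.ndarray            # mean pairwise correlation per time-in-burst bin
    profile_times_ms: np.ndarray
    n_pairs: int
    n_skipped_pairs: int           # zero-variance pairs
    normalized: float | None = None


def _mean_pairwise_corr(counts: np.ndarray) -> tuple[float, int, int]:
    """Mean off-diagonal Pearson correlation of rows of ``counts``."""
    sd = counts.std(axis=1)
    keep = sd > 0
    skipped_units = int(np.count_nonzero(~keep))
    kept = counts[keep]
    n = kept.shape[0]
    total_pairs = counts.shape[0] * (counts.shape[0] - 1) // 2
    if n < 2:
        return np.nan, 0, total_pairs
    c = np.corrcoef(kept)
    iu = np.triu_indices(n, k=1)
    n_pairs = iu[0].size
    return float(c[iu].mean()), n_pairs, total_pairs - n_pairs


def synchronization(spikes: SpikeRecord, bursts: list[NetworkBurst],
                    bin_ms: int = DEFAULT_BIN_MS, window_ms: int = 1000,
                    baseline: float | None = None) -> SynchronizationResult:
    """Average pairwise Pearson correlation of binned in-burst spike counts.

    Counts are taken per unit in time bins inside each burst window (aligned
    at initiation).  The per-unit count vectors are standardized (z-scored;
    Pearson correlation is invariant to this, the standardization matters
    only for reporting) and correlated pairwise over all in-burst bins; the
    profile correlates units bin-by-bin across bursts.  Passing ``baseline``
    (another run's overall scalar) adds a normalized score.
    """
    act = active_units(spikes)
    if act.size < 2:
        raise ValueError("need at least two active units")
    if not bursts:
        raise ValueError("need at least one burst")
    n_bins = window_ms // bin_ms
    # counts[unit, burst, bin_in_burst]
    counts = np.zeros((act.size, len(bursts), n_bins))
    unit_index = {u: k for k, u in enumerate(act)}
    mask = np.isin(spikes.units, act)
    times = spikes.times[mask]
    units = spikes.units[mask]
    for bi, b in enumerate(bursts):
        sel = (times >= b.t_start) & (times < b.t_start + window_ms)
        rel = ((times[sel] - b.t_start) // bin_ms).astype(int)
        for u, r in zip(units[sel], rel):
            counts[unit_index[u], bi, r] += 1
    # participate-in-bursts criterion: keep units with any in-burst spikes
    in_burst = counts.sum(axis=(1, 2)) > 0
    counts = counts[in_burst]

    flat = counts.reshape(counts.shape[0], -1)
    overall, n_pairs, skipped = _mean_pairwise_corr(flat)
    profile = np.full(n_bins, np.nan)
    if len(bursts) >= 2:
        for k in range(n_bins):
            profile[k] = _mean_pairwise_corr(counts[:, :, k])[0]
    return SynchronizationResult(
        overall=overall, profile=profile,
        profile_times_ms=np.arange(n_bins) * float(bin_ms),
        n_pairs=n_pairs, n_skipped_pairs=skipped,
        normalized=(overall / baseline) if baseline else None)


def burst_statistics(spikes: SpikeRecord, bursts: list[NetworkBurst],
                     n_units: int | None = None) -> BurstStatistics:
    """Headline per-run burst statistics (rates use the full record span)."""
    minutes = spikes.duration_ms / 60_000.0
    seconds = spikes.duration_ms / 1000.0
    n_units = n_units if n_units is not None else max(active_units(spikes).size, 1)
    classify_bursts(bursts, n_units)
    if not bursts:
        return BurstStatistics(0.0, np.nan, np.nan, np.nan,
                               spikes.n_spikes / seconds, np.nan, np.nan,
                               np.nan, spikes.n_spikes / seconds, 0)
    in_burst = sum(b.n_spikes for b in bursts)
    burst_time_s = sum(b.duration_ms for b in bursts) / 1000.0
    out_rate = (spikes.n_spikes - in_burst) / max(seconds - burst_time_s, 1e-9)
    return BurstStatistics(
        bursts_per_min=len(bursts) / minutes,
        mean_duration_ms=float(np.mean([b.duration_ms for b in bursts])),
        mean_spikes_per_burst=float(np.mean([b.n_spikes for b in bursts])),
        mean_peak_rate=float(np.mean([b.peak_rate for b in bursts])),
        global_spike_rate=spikes.n_spikes / seconds,
        participation_ratio=float(np.mean(
            [b.n_participating / n_units for b in bursts])),
        full_burst_fraction=float(np.mean(
            [b.label == "full" for b in bursts])),
        mean_time_to_peak_ms=float(np.mean(
            [b.time_to_peak_ms for b in bursts])),
        interburst_rate=float(out_rate),
        n_bursts=len(bursts))


# --------------------------------------------------------------------------
# burst-aligned state-trace analyses
# --------------------------------------------------------------------------

def _covered(trace: StateTrace, b: NetworkBurst, pad_ms: float = 0.0) -> bool:
    t_last = trace.start_ms + (trace.n_samples - 1) * trace.stride_ms
    return b.t_start >= trace.start_ms and b.t_end + pad_ms <= t_last


def pool_burst_average(trace: StateTrace, bursts: list[NetworkBurst],
                       var: str, window_ms: int = 1000,
                       participants_only: bool = True):
    """Mean state variable vs time-in-burst, averaged over bursts and neurons.

    Bursts not covered by the trace are excluded (with a warning).  Returns
    ``(time_in_burst_ms, mean_curve)``.
    """
    import warnings
    arr = trace.arrays[var]
    n_bins = window_ms // trace.stride_ms
    curves = []
    id_to_col = {int(u): k for k, u in enumerate(trace.neurons)}
    for b in bursts:
        if not _covered(trace, b):
            warnings.warn("burst outside trace coverage: excluded", stacklevel=2)
            continue
        i0 = trace.index_of(b.t_start)
        seg = arr[i0:i0 + n_bins].astype(float)
        if seg.shape[0] < n_bins:
            seg = np.pad(seg, ((0, n_bins - seg.shape[0]), (0, 0)),
                         constant_values=np.nan)
        if participants_only:
            cols = [id_to_col[int(u)] for u in b.participants
                    if int(u) in id_to_col]
            seg = seg[:, cols]
        curves.append(np.nanmean(seg, axis=1))
    if not curves:
        raise ValueError("no bursts covered by the trace")
    t = np.arange(n_bins) * trace.stride_ms
    return t, np.nanmean(np.stack(curves), axis=0)


def fraction_below_at_termination(trace: StateTrace, bursts: list[NetworkBurst],
                                  var: str, threshold: float,
                                  participants_only: bool = True) -> float:
    """Mean fraction of (participating) neurons with ``var`` < threshold at
    each burst's termination time, averaged over bursts."""
    arr = trace.arrays[var]
    id_to_col = {int(u): k for k, u in enumerate(trace.neurons)}
    fracs = []
    for b in bursts:
        if not _covered(trace, b):
            continue
        row = arr[trace.index_of(b.t_end)].astype(float)
        if participants_only:
            cols = [id_to_col[int(u)] for u in b.participants
                    if int(u) in id_to_col]
            row = row[cols]
        if row.size:
            fracs.append(np.mean(row < threshold))
    if not fracs:
        raise ValueError("no bursts covered by the trace")
    return float(np.mean(fracs))


def cumulative_release_per_neuron(trace: StateTrace, bursts: list[NetworkBurst],
                                  horizon_ms: int = 300,
                                  participants_only: bool = True) -> float:
    """Mean cumulative vesicles released per neuron within the first
    ``horizon_ms`` of a burst, averaged over bursts."""
    rel = trace.arrays["released"]
    id_to_col = {int(u): k for k, u in enumerate(trace.neurons)}
    n_bins = horizon_ms // trace.stride_ms
    vals = []
    for b in bursts:
        if not _covered(trace, b, pad_ms=0):
            continue
        i0 = trace.index_of(b.t_start)
        seg = rel[i0:i0 + n_bins].astype(float)
        if participants_only:
            cols = [id_to_col[int(u)] for u in b.participants
                    if int(u) in id_to_col]
            seg = seg[:, cols]
        if seg.size:
            vals.append(seg.sum(axis=0).mean())
    if not vals:
        raise ValueError("no bursts covered by the trace")
    return float(np.mean(vals))


def pool_consumption_per_burst(trace: StateTrace, bursts: list[NetworkBurst],
                               var: str = "rep",
                               participants_only: bool = True) -> float:
    """Mean per-neuron decrease of a pool from burst start to burst end."""
    arr = trace.arrays[var]
    id_to_col = {int(u): k for k, u in enumerate(trace.neurons)}
    vals = []
    for b in bursts:
        if not _covered(trace, b):
            continue
        start = arr[trace.index_of(b.t_start)].astype(float)
        end = arr[trace.index_of(b.t_end)].astype(float)
        drop = start - end
        if participants_only:
            cols = [id_to_col[int(u)] for u in b.participants
                    if int(u) in id_to_col]
            drop = drop[cols]
        if drop.size:
            vals.append(drop.mean())
    if not vals:
        raise ValueError("no bursts covered by the trace")
    return float(np.mean(vals))


def raster_export(spikes: SpikeRecord, out_path, max_points: int = 200_000):
    """Color-coded raster: one row per unit, spikes colored by the inverse
    mean of their two adjacent inter-spike intervals (s^-1).

    Single-spike units get a neutral gray mark.  Returns the output path.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if spikes.n_spikes == 0:
        raise ValueError("empty spike record")
    xs, ys, cs = [], [], []
    for unit, t in enumerate(spikes.per_unit()):
        if t.size == 0:
            continue
        freq = np.full(t.size, np.nan)
        if t.size >= 2:
            isi = np.diff(t) / 1000.0                  # s
            mean_isi = np.empty(t.size)
            mean_isi[0] = isi[0]
            mean_isi[-1] = isi[-1]
            if t.size > 2:
                mean_isi[1:-1] = (isi[:-1] + isi[1:]) / 2.0
            with np.errstate(divide="ignore"):
                freq = 1.0 / mean_isi
        xs.append(t / 1000.0)
        ys.append(np.full(t.size, unit))
        cs.append(freq)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    c = np.concatenate(cs)
    if x.size > max_points:
        idx = np.linspace(0, x.size - 1, max_points).astype(int)
        x, y, c = x[idx], y[idx], c[idx]
    fig, ax = plt.subplots(figsize=(10, 5))
    neutral = np.isnan(c)
    ax.scatter(x[neutral], y[neutral], s=1, c="gray")
    sc = ax.scatter(x[~neutral], y[~neutral], s=1, c=c[~neutral],
                    cmap="viridis", vmin=0)
    fig.colorbar(sc, ax=ax, label="instantaneous rate (s$^{-1}$)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("unit")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
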