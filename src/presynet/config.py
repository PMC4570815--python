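"""Simulation configuration: baseline parameter set, validation, file round-trip.

Every model constant lives on :class:`SimulationConfig`.  Defaults are the
baseline parameter set of the model (cortical-culture calibration); config
files use the original variable names (``average_EPSP``,
``single_vesicle_max_RRP_repleneshing_k``, ...) so a file can be diffed
against the published parameter table directly.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range parameter values."""


@dataclass(frozen=True)
class SimulationConfig:
    # --- general / topology ---
    mea_dims: float = 100.0            # side length of the square plate, a.u.
    n_neurons: int = 800
    connectivity_ratio: float = 0.05   # realized directed edges / n(n-1)
    inhibitory_neuron_ratio: float = 0.30
    weight_mu: float = -0.874          # lognormal synaptic-weight parameters
    weight_sigma: float = 1.026
    # Pre-truncation mean of the rescaled lognormal weight distribution
    # (None keeps the raw scale, mean exp(mu + sigma^2/2) ~ 0.707; truncation
    # at A_max lowers the realized mean, to ~3.2 at the default).  The
    # lognormal parameters set the shape of connection heterogeneity; the
    # overall scale is the model's operating-point calibration, chosen so the
    # baseline network reproduces the target regime of recurrent
    # multi-hundred-millisecond network bursts (~10 per minute, majority
    # participation) with ongoing inter-burst activity.  See docs/methods.md.
    weight_mean: float | None = 5.0
    a_max: float = 10.0                # weight truncation |A_ij| < A_max
    pareto_shape: float = 0.25         # generalized-Pareto out-degree shape
    kernel_trials: int | None = None   # distance-kernel binomial n (default n-1)
    kernel_p: float = 0.05             # distance-kernel binomial p

    # --- voltage (mV, ms) ---
    epsp_mv: float = 3.16              # q: PSP per released vesicle (pooled synapse)
    v_rest: float = -70.0
    v_max: float = 50.0                # peak AP voltage (display only)
    v_hyp: float = -77.0               # post-spike reset
    ap_threshold: float = -30.0
    tau_m: float = 52.0
    tau_arp: float = 3.0               # absolute refractory period, ms

    # --- vesicle pools ---
    rrp_full: float = 10.0
    rep_full: float = 20.0
    rp_full: float = 170.0
    r_max: float = 7.3e-4              # max per-vesicle ReP->RRP priming rate
    r_max_per_second: bool = False     # alternative unit reading of r_max
    tau_rep_replenish: float = 30000.0  # RP -> ReP, ms
    tau_rp_replenish: float = 50000.0   # -> RP refill, ms

    # --- calcium (uM, ms) ---
    ca_fast_max: float = 13.6
    ca_slow_max: float = 1.36
    ap_influx_slow: float = 0.5
    tau_ca_fast: float = 1.0
    tau_ca_slow: float = 31.0
    ca_rest: float = 0.05
    kd: float = 2.3
    p_max: float = 0.15                # documented curve maximum (informational)
    p_basal: float = 7.5e-4            # documented basal Pr per RRP (informational)
    alpha: float = 0.175               # release-curve sigmoid parameters
    beta: float = 2.35
    gamma: float = 0.78
    delta: float = -3.6e-3

    # --- manipulations ---
    spontaneous_pct: float = 0.0       # +1.0 doubles Pr at resting calcium

    # --- run control ---
    duration_ms: int = 600_000
    dt_ms: float = 1.0
    warmup_ms: int = 60_000
    seed: int = 0
    synapses_per_neuron: int = 1       # k independent presynaptic compartments

    # --- trace recording ---
    record_trace: bool = False
    trace_vars: tuple[str, ...] = ("rrp", "rep", "released")
    trace_stride: int = 1
    trace_start_ms: int = 0
    trace_neurons: tuple[int, ...] | None = None  # None = all
    trace_dtype: str = "float32"

    def __post_init__(self) -> None:
        self.validate()

    # dataclasses.replace re-runs __post_init__, so derived configs stay valid.
    def replace(self, **changes: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def validate(self) -> None:
        c = self
        checks = [
            (c.n_neurons >= 2, "n_neurons must be >= 2"),
            (c.mea_dims > 0, "mea_dims must be positive"),
            (0 < c.connectivity_ratio < 1, "connectivity_ratio must be in (0,1)"),
            (0 <= c.inhibitory_neuron_ratio <= 1,
             "inhibitory_neuron_ratio must be in [0,1]"),
            (c.a_max > 0, "a_max must be positive"),
            (c.tau_m > 0, "voltage_tau must be positive"),
            (c.tau_arp >= 0, "refractory_period must be >= 0"),
            (c.ap_threshold > c.v_rest, "AP_threshold must exceed resting voltage"),
            (c.rrp_full > 0 and c.rep_full > 0 and c.rp_full > 0,
             "pool capacities must be positive"),
            (c.r_max > 0, "single_vesicle_max_RRP_repleneshing_k must be positive"),
            (c.tau_rep_replenish > 0, "ReP_repleneshing_tau must be positive"),
            (c.tau_rp_replenish > 0, "RP_repleneshing_tau must be positive"),
            (c.tau_ca_fast > 0, "calcium_fast_efflux_tau must be positive"),
            (c.tau_ca_slow > 0, "calcium_slow_efflux_tau must be positive"),
            (c.ca_rest > 0, "basal_calcium must be positive"),
            (c.kd > 0, "Kd must be positive"),
            (c.ca_fast_max > 0 and c.ca_slow_max > 0,
             "calcium maxima must be positive"),
            (c.spontaneous_pct > -1, "spontaneous_pct must exceed -1"),
            (c.duration_ms > 0, "duration_ms must be positive"),
            (c.dt_ms == 1.0, "the engine integrates on a fixed 1-ms grid"),
            (0 <= c.warmup_ms < c.duration_ms,
             "warmup_ms must be shorter than duration_ms"),
            (c.synapses_per_neuron >= 1, "synapses_per_neuron must be >= 1"),
            (c.trace_stride >= 1, "trace_stride must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    # -- derived quantities ------------------------------------------------
    @property
    def theta_rel(self) -> float:
        """Spike threshold relative to rest (mV)."""
        return self.ap_threshold - self.v_rest

    @property
    def v_hyp_rel(self) -> float:
        """Post-spike reset voltage relative to rest (mV)."""
        return self.v_hyp - self.v_rest

    @property
    def r_max_per_ms(self) -> float:
        """Priming rate on the 1-ms integration grid."""
        return self.r_max / 1000.0 if self.r_max_per_second else self.r_max


# Mapping from the published parameter-table variable names to config fields.
TABLE_KEYS: dict[str, str] = {
    "MEA_Dims": "mea_dims",
    "N": "n_neurons",
    "Connectivity_ratio": "connectivity_ratio",
    "inhibitory_neuron_ratio": "inhibitory_neuron_ratio",
    "Weight_params_mu": "weight_mu",
    "Weight_params_sigma": "weight_sigma",
    "A_max": "a_max",
    "average_EPSP": "epsp_mv",
    "standard_voltage": "v_rest",
    "max_voltage": "v_max",
    "hyper_polarize_voltage": "v_hyp",
    "AP_threshold": "ap_threshold",
    "voltage_tau": "tau_m",
    "refractory_period": "tau_arp",
    "standard_RRP": "rrp_full",
    "standard_ReP": "rep_full",
    "standard_RP": "rp_full",
    "single_vesicle_max_RRP_repleneshing_k": "r_max",
    "ReP_repleneshing_tau": "tau_rep_replenish",
    "RP_repleneshing_tau": "tau_rp_replenish",
    "fast_calcium_max": "ca_fast_max",
    "slow_calcium_max": "ca_slow_max",
    "slow_calcium_AP_influx": "ap_influx_slow",
    "calcium_fast_efflux_tau": "tau_ca_fast",
    "calcium_slow_efflux_tau": "tau_ca_slow",
    "basal_calcium": "ca_rest",
    "Kd": "kd",
    "p_max": "p_max",
    "p_basal_perRRPpool": "p_basal",
    "calcium_release_A": "alpha",
    "calcium_release_B": "beta",
    "calcium_release_C": "gamma",
    "calcium_release_D": "delta",
}

# Extra (non-table) keys accepted in config files, by section.
_EXTRA_KEYS: dict[str, str] = {
    "weight_mean": "weight_mean",
    "pareto_shape": "pareto_shape",
    "kernel_trials": "kernel_trials",
    "kernel_p": "kernel_p",
    "r_max_per_second": "r_max_per_second",
    "spontaneous_pct": "spontaneous_pct",
    "duration_ms": "duration_ms",
    "dt_ms": "dt_ms",
    "warmup_ms": "warmup_ms",
    "seed": "seed",
    "synapses_per_neuron": "synapses_per_neuron",
    "record_trace": "record_trace",
    "trace_vars": "trace_vars",
    "trace_stride": "trace_stride",
    "trace_start_ms": "trace_start_ms",
    "trace_neurons": "trace_neurons",
    "trace_dtype": "trace_dtype",
}

_ALL_KEYS = {**TABLE_KEYS, **_EXTRA_KEYS}

_SECTIONS = ("general", "voltage", "pools", "calcium", "manipulations", "run", "trace")


def _coerce(key: str, value: Any) -> Any:
    if key == "MEA_Dims" and isinstance(value, str):
        # accept the "100x100" notation for the square plate
        side = value.lower().split("x")[0]
        return float(side)
    if key in ("Connectivity_ratio", "inhibitory_neuron_ratio") and isinstance(value, str):
        if value.endswith("%"):
            return float(value[:-1]) / 100.0
    if isinstance(value, str) and value.endswith("%"):
        return float(value[:-1]) / 100.0
    if key in ("trace_vars", "trace_neurons") and isinstance(value, list):
        return tuple(value)
    return value


def config_from_mapping(mapping: dict[str, Any]) -> SimulationConfig:
    """Build a config from a flat or sectioned key/value mapping."""
    flat: dict[str, Any] = {}
    for key, value in mapping.items():
        if key in _SECTIONS and isinstance(value, dict):
            for k, v in value.items():
                flat[k] = v
        else:
            flat[key] = value
    kwargs: dict[str, Any] = {}
    for key, value in flat.items():
        if key not in _ALL_KEYS:
            raise ConfigError(f"unknown configuration key: {key!r}")
        kwargs[_ALL_KEYS[key]] = _coerce(key, value)
    return SimulationConfig(**kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML config file; an empty file yields the baseline defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return SimulationConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return config_from_mapping(data)


_FIELD_TO_TABLE = {v: k for k, v in TABLE_KEYS.items()}


def config_to_mapping(config: SimulationConfig) -> dict[str, Any]:
    """Serialize a config using the published variable names where they exist."""
    out: dict[str, Any] = {}
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, tuple):
            value = list(value)
        out[_FIELD_TO_TABLE.get(f.name, f.name)] = value
    return out


def save_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_mapping(config), sort_keys=False))
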