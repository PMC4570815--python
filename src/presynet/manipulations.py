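"""In-silico manipulations of presynaptic release, as pure config transforms.

Each function returns a new :class:`SimulationConfig`; the input is never
modified.  The manipulations mirror the experimental interventions the model
emulates:

* asynchronous release (strontium / DOC2B): slower calcium clearance —
  both efflux time constants scaled by the same factor, in excitatory and
  inhibitory neurons alike;
* spontaneous release (DOC2B mutant): higher release probability at resting
  calcium, with the high-calcium limb of the release curve unchanged;
* priming rate (Munc13-1): the maximum ReP->RRP vesicle transition rate
  R_max scaled (the coupled backward rate follows automatically);
* gain sweeps over EPSP size and connectivity ratio, and network scaling
  (more neurons and/or independent synaptic compartments per neuron).
"""
from __future__ import annotations

from dataclasses import dataclass

from .config import SimulationConfig

__all__ = [
    "Manipulation",
    "apply_async",
    "apply_spontaneous",
    "apply_priming",
    "apply_epsp_gain",
    "apply_gain_sweep",
    "apply_scale",
    "apply_manipulation",
]

_KINDS = ("async_release", "spontaneous_release", "priming_rate",
          "epsp_gain", "connectivity", "network_scale")


@dataclass(frozen=True)
class Manipulation:
    """A named manipulation with a signed magnitude (+1.0 means '+100 %')."""

    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown manipulation kind {self.kind!r}")
        if self.kind in ("async_release", "spontaneous_release") \
                and self.magnitude <= -1:
            raise ValueError("magnitude must exceed -1 for multiplicative kinds")


def apply_async(config: SimulationConfig, pct: float) -> SimulationConfig:
    """Scale both calcium-clearance time constants by (1 + pct).

    Slower clearance (pct > 0) leaves residual calcium in the terminal for
    longer, shifting vesicle release from the synchronous into the
    asynchronous window.
    """
    if pct <= -1:
        raise ValueError("pct must exceed -1")
    return config.replace(tau_ca_fast=config.tau_ca_fast * (1 + pct),
                          tau_ca_slow=config.tau_ca_slow * (1 + pct))


def apply_spontaneous(config: SimulationConfig, pct: float) -> SimulationConfig:
    """Raise the release probability at resting calcium by a factor (1 + pct).

    Implemented as a blended offset on the release curve that equals
    pct * Pr(ca_rest) at rest and vanishes at saturating calcium, so the
    evoked (high-calcium) limb is untouched (see
    :func:`presynet.synapse.release_probability`).
    """
    if pct <= -1:
        raise ValueError("pct must exceed -1")
    return config.replace(spontaneous_pct=config.spontaneous_pct + pct)


def apply_priming(config: SimulationConfig, factor: float) -> SimulationConfig:
    """Scale the maximum per-vesicle priming rate R_max by ``factor``."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return config.replace(r_max=config.r_max * factor)


def apply_epsp_gain(config: SimulationConfig, factor: float) -> SimulationConfig:
    """Scale the per-vesicle postsynaptic potential q by ``factor``."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return config.replace(epsp_mv=config.epsp_mv * factor)


def apply_gain_sweep(config: SimulationConfig, epsp_factors,
                     connectivity_ratios) -> list[SimulationConfig]:
    """Grid of configs over EPSP gain x connectivity ratio."""
    out = []
    for f in epsp_factors:
        for ratio in connectivity_ratios:
            out.append(apply_epsp_gain(config, f).replace(
                connectivity_ratio=ratio))
    return out


def apply_scale(config: SimulationConfig, n_neurons_factor: float = 1.0,
                synapses_per_neuron: int | None = None) -> SimulationConfig:
    """Scale network size and/or per-neuron synaptic compartments.

    The per-compartment EPSP is rescaled inside the engine (q / k) so the
    expected postsynaptic drive per AP is unchanged.
    """
    if n_neurons_factor < 1:
        raise ValueError("n_neurons_factor must be >= 1")
    changes: dict = {"n_neurons": int(round(config.n_neurons * n_neurons_factor))}
    if synapses_per_neuron is not None:
        if synapses_per_neuron < 1:
            raise ValueError("synapses_per_neuron must be >= 1")
        changes["synapses_per_neuron"] = synapses_per_neuron
    return config.replace(**changes)


def apply_manipulation(config: SimulationConfig,
                       m: Manipulation) -> SimulationConfig:
    if m.kind == "async_release":
        return apply_async(config, m.magnitude)
    if m.kind == "spontaneous_release":
        return apply_spontaneous(config, m.magnitude)
    if m.kind == "priming_rate":
        return apply_priming(config, m.magnitude)
    if m.kind == "epsp_gain":
        return apply_epsp_gain(config, m.magnitude)
    if m.kind == "connectivity":
        return config.replace(connectivity_ratio=m.magnitude)
    if m.kind == "network_scale":
        return apply_scale(config, m.magnitude)
    raise ValueError(f"unknown manipulation kind {m.kind!r}")
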