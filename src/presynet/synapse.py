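"""Presynaptic compartment dynamics.

Each neuron carries one (or k independent) presynaptic compartment(s) holding

* two residual free-calcium pools (fast and slow) above a constant resting
  level, each cleared with its own exponential time constant;
* a sigmoidal calcium -> per-vesicle release-probability curve (a Calyx-of-Held
  release-rate curve rescaled to the lower Pr of cortical synapses);
* three vesicle pools -- readily releasable (RRP), recycling (ReP) and reserve
  (RP) -- with bidirectional transfer, a Michaelis-Menten calcium-dependent
  priming step (ReP -> RRP), and binomial vesicle release from the RRP.

All functions are vectorized over neurons/compartments; scalars work too.
Calcium decay uses exact exponential factors per 1-ms step (Euler would be
degenerate at tau_fast = dt); vesicle pools use forward Euler with dt = 1 ms.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig

__all__ = [
    "ReleaseParams",
    "release_probability",
    "step_calcium",
    "priming_time_constant",
    "draw_release",
    "step_pools",
]


@dataclass(frozen=True)
class ReleaseParams:
    """The presynaptic parameter bundle used by the stepping functions."""

    alpha: float = 0.175
    beta: float = 2.35
    gamma: float = 0.78
    delta: float = -3.6e-3
    kd: float = 2.3                  # uM, priming half-saturation
    r_max: float = 7.3e-4            # per-vesicle ReP->RRP rate, per ms
    rrp_full: float = 10.0
    rep_full: float = 20.0
    rp_full: float = 170.0
    tau_rep_replenish: float = 30000.0   # RP -> ReP, ms
    tau_rp_replenish: float = 50000.0    # -> RP refill, ms
    ca_rest: float = 0.05            # uM
    ca_fast_max: float = 13.6        # uM
    ca_slow_max: float = 1.36        # uM
    ap_influx_slow: float = 0.5      # uM per AP into the slow pool
    tau_ca_fast: float = 1.0         # ms
    tau_ca_slow: float = 31.0        # ms
    spontaneous_pct: float = 0.0     # spontaneous-release manipulation

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "ReleaseParams":
        return cls(
            alpha=config.alpha, beta=config.beta, gamma=config.gamma,
            delta=config.delta, kd=config.kd, r_max=config.r_max_per_ms,
            rrp_full=config.rrp_full, rep_full=config.rep_full,
            rp_full=config.rp_full,
            tau_rep_replenish=config.tau_rep_replenish,
            tau_rp_replenish=config.tau_rp_replenish,
            ca_rest=config.ca_rest, ca_fast_max=config.ca_fast_max,
            ca_slow_max=config.ca_slow_max,
            ap_influx_slow=config.ap_influx_slow,
            tau_ca_fast=config.tau_ca_fast, tau_ca_slow=config.tau_ca_slow,
            spontaneous_pct=config.spontaneous_pct,
        )

    @property
    def ca_total_max(self) -> float:
        return self.ca_fast_max + self.ca_slow_max + self.ca_rest


def _sigmoid(ca_total, params: ReleaseParams):
    return 1.0 / (1.0 + np.exp(-params.beta * np.log10(ca_total) + params.gamma))


def release_probability(ca_total, params: ReleaseParams):
    """Per-vesicle release probability at total free calcium ``ca_total`` (uM).

    Pr = alpha / (1 + exp(-beta*log10(Ca) + gamma)) + delta, clamped to [0, 1].

    The spontaneous-release manipulation adds a blended offset
    ``pct * Pr(ca_rest) * w(Ca)`` where the weight w equals 1 at resting
    calcium and vanishes at saturating calcium, so the resting-state Pr is
    scaled by (1 + pct) while the high-calcium limb of the curve is unchanged.
    """
    ca_total = np.asarray(ca_total, dtype=float)
    if np.any(ca_total <= 0):
        raise ValueError("ca_total must be strictly positive (uM)")
    pr = params.alpha * _sigmoid(ca_total, params) + params.delta
    if params.spontaneous_pct != 0.0:
        pr_rest = params.alpha * _sigmoid(params.ca_rest, params) + params.delta
        w = (1.0 - _sigmoid(ca_total, params)) / (1.0 - _sigmoid(params.ca_rest, params))
        pr = pr + params.spontaneous_pct * pr_rest * w
    return np.clip(pr, 0.0, 1.0)[()]


def step_calcium(ca_fast, ca_slow, ap_fired, dt: float, params: ReleaseParams):
    """Advance the residual calcium pools by one step of length ``dt`` ms.

    Both pools decay by their exact exponential factor.  If an AP fired this
    step, the fast pool is set to its ceiling CA_FAST and the slow pool gains
    a fixed influx (0.5 uM by default), clamped at CA_SLOW.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ca_fast = np.asarray(ca_fast, dtype=float) * np.exp(-dt / params.tau_ca_fast)
    ca_slow = np.asarray(ca_slow, dtype=float) * np.exp(-dt / params.tau_ca_slow)
    ap = np.asarray(ap_fired, dtype=bool)
    ca_fast = np.where(ap, params.ca_fast_max, ca_fast)
    ca_slow = np.where(ap, np.minimum(ca_slow + params.ap_influx_slow,
                                      params.ca_slow_max), ca_slow)
    return ca_fast[()], ca_slow[()]


def priming_rate(ca_total, params: ReleaseParams):
    """Per-vesicle ReP->RRP priming rate (per ms): r_max * Ca / (Ca + Kd)."""
    ca_total = np.asarray(ca_total, dtype=float)
    return (params.r_max * ca_total / (ca_total + params.kd))[()]


def priming_time_constant(ca_total, params: ReleaseParams):
    """Calcium-dependent forward priming time constant tau_ReP->RRP (ms).

    tau = 1 / (r_max * Ca/(Ca+Kd)); infinite (no priming) at zero calcium.
    The backward constant is coupled: tau_RRP->ReP = tau * RRP_full/ReP_full.
    """
    rate = np.asarray(priming_rate(ca_total, params), dtype=float)
    with np.errstate(divide="ignore"):
        tau = np.where(rate > 0, 1.0 / np.where(rate > 0, rate, 1.0), np.inf)
    return tau[()]


def draw_release(rrp, pr, rng: np.random.Generator):
    """Binomial vesicle release: X ~ B(floor(RRP), Pr)."""
    trials = np.floor(np.asarray(rrp, dtype=float)).astype(np.int64)
    pr = np.asarray(pr, dtype=float)
    if np.any((pr < 0) | (pr > 1)):
        raise ValueError("pr must lie in [0, 1]")
    return rng.binomial(trials, np.broadcast_to(pr, trials.shape))


def step_pools(rrp, rep, rp, released, ca_total, dt: float,
               params: ReleaseParams):
    """Forward-Euler step of the three-pool vesicle system.

    Fluxes (per ms):
        ReP -> RRP : ReP / tau_f            (calcium-dependent priming)
        RRP -> ReP : RRP / tau_b,  tau_b = tau_f * RRP_full / ReP_full
        RP  -> ReP : RP / tau_RP->ReP
        ReP -> RP  : ReP / tau_ReP->RP, tau_ReP->RP = tau_RP->ReP * ReP_full / RP_full
        -> RP      : (RP_full - RP) / tau_->RP      (external refill source)
    Release is removed from the RRP; pools are clamped to [0, capacity]
    afterwards.  Inter-pool transfers conserve vesicles exactly before
    clamping; only release and the external refill change the grand total.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rrp = np.asarray(rrp, dtype=float)
    rep = np.asarray(rep, dtype=float)
    rp = np.asarray(rp, dtype=float)
    released = np.asarray(released, dtype=float)
    if np.any(released > np.floor(rrp) + 1e-9):
        raise ValueError("released exceeds floor(RRP): contract violation")

    k_f = priming_rate(ca_total, params)             # per-vesicle ReP->RRP
    k_b = k_f * params.rep_full / params.rrp_full    # per-vesicle RRP->ReP
    k_rp_rep = 1.0 / params.tau_rep_replenish        # RP->ReP
    # tau_ReP->RP = tau_RP->ReP * ReP_full/RP_full, hence the rate scales up
    k_rep_rp = k_rp_rep * params.rp_full / params.rep_full  # ReP->RP
    k_refill = 1.0 / params.tau_rp_replenish

    f_prime = rep * k_f * dt          # ReP -> RRP
    f_demote = rrp * k_b * dt         # RRP -> ReP
    f_refill_rep = rp * k_rp_rep * dt     # RP -> ReP
    f_return = rep * k_rep_rp * dt        # ReP -> RP
    f_source = (params.rp_full - rp) * k_refill * dt

    rrp_new = rrp + f_prime - f_demote - released
    rep_new = rep + f_demote - f_prime + f_refill_rep - f_return
    rp_new = rp + f_source + f_return - f_refill_rep

    rrp_new = np.clip(rrp_new, 0.0, params.rrp_full)
    rep_new = np.clip(rep_new, 0.0, params.rep_full)
    rp_new = np.clip(rp_new, 0.0, params.rp_full)
    return rrp_new[()], rep_new[()], rp_new[()]
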