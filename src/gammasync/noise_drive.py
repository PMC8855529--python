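"""Uncorrelated Poisson noise drive.

Every neuron receives input from its own group of ``N_p`` Poisson sources,
independent across neurons and across networks.  The drive is parameterized
by the mean input ``mu_v`` and the noise strength ``sigma2`` (its variance)
rather than by rate and per-spike amplitude directly:

    lambda  = mu_v**2 / (sigma2 * N_p)      rate per source, Hz
    Delta_v = sigma2 / mu_v                 dimensionless per-spike strength

so that ``lambda * N_p * Delta_v = mu_v`` and
``lambda * N_p * Delta_v**2 = sigma2`` (recovery identities).  Raising
``sigma2`` at fixed ``mu_v`` therefore makes individual noise spikes stronger
but rarer.  Network 2 receives the reduced rate ``lambda_2 = p * lambda_1``
(Poisson rate ratio p), which sets the natural-frequency mismatch between the
two networks; the per-spike strength is identical everywhere.

Each arriving noise spike depolarizes the target by
``Delta_v * (V_T - V_r)`` mV — at ``Delta_v = 1`` exactly the threshold-to-
reset gap, i.e. enough to trigger a spike regardless of the current membrane
potential.  The drive is delivered as an equivalent one-step current pulse
scaled so the per-spike voltage effect is independent of the integration
step (``literal_eq14=True`` switches to a fixed current of
``g_P (V_T - V_r) Delta_v`` per spike, whose voltage effect then scales
with dt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import AdExParams

__all__ = [
    "NoiseParams",
    "poisson_rate",
    "input_strength",
    "network2_rate",
    "draw_spike_counts",
    "external_current",
]


@dataclass(frozen=True)
class NoiseParams:
    """Free parameters of the noise drive.

    ``inh_noise_fraction`` scales the rate delivered to inhibitory
    populations in the excitatory-inhibitory scenarios, where the I cells
    receive a lower proportion of noise so their spiking is not dominated by
    it (which would collapse the PING rhythm).  Purely inhibitory (ING)
    networks receive the full rate.
    """

    mu_v: float = 300.0
    sigma2: float = 1.0
    p_ratio: float = 0.75
    N_p: int = 800
    g_P: float = 1.0              # nS, unit-carrying constant
    inh_noise_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.mu_v <= 0:
            raise ValueError("mu_v must be positive")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not 0.0 <= self.p_ratio <= 1.0:
            raise ValueError("p_ratio must lie in [0, 1]")
        if self.N_p < 1:
            raise ValueError("N_p must be at least 1")
        if not 0.0 <= self.inh_noise_fraction <= 1.0:
            raise ValueError("inh_noise_fraction must lie in [0, 1]")


def poisson_rate(mu_v: float, sigma2: float, N_p: int) -> float:
    """Rate per Poisson source in Hz: lambda = mu_v^2 / (sigma2 * N_p)."""
    if mu_v <= 0 or N_p <= 0:
        raise ValueError("mu_v and N_p must be positive")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive (sigma2 -> 0 is the "
                         "infinite-rate limit)")
    return mu_v * mu_v / (sigma2 * N_p)


def input_strength(sigma2: float, mu_v: float) -> float:
    """Dimensionless per-spike input strength Delta_v = sigma2 / mu_v."""
    if mu_v <= 0:
        raise ValueError("mu_v must be positive")
    return sigma2 / mu_v


def network2_rate(lambda1: float, p_ratio: float) -> float:
    """Reduced source rate of network 2: lambda_2 = p * lambda_1."""
    if not 0.0 <= p_ratio <= 1.0:
        raise ValueError("p_ratio must lie in [0, 1]")
    return p_ratio * lambda1


def draw_spike_counts(
    rate: float,
    N_p: int,
    dt: float,
    n_neurons: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson spike counts per neuron for one step of dt ms.

    The aggregate of ``N_p`` independent sources at ``rate`` Hz is itself
    Poisson with mean ``N_p * rate * dt / 1000``, so the per-source trains
    are never materialized.  Independence across neurons comes from the
    independent draws of a single seeded stream.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    mean = N_p * rate * dt / 1000.0
    return rng.poisson(mean, size=n_neurons)


def external_current(
    counts: np.ndarray | float,
    delta_v: float,
    params: AdExParams,
    g_P: float = 1.0,
    dt: float = 0.05,
    literal_eq14: bool = False,
) -> np.ndarray:
    """External noise current I_ext in pA for one integration step.

    Default form: each noise spike moves the membrane by exactly
    ``delta_v * (V_T - V_r)`` mV irrespective of dt, delivered as the
    one-step current ``C * delta_v * (V_T - V_r) * P / dt``.  With
    ``literal_eq14`` the current is ``g_P * (V_T - V_r) * delta_v * P``
    instead (per-spike voltage effect then proportional to dt).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("spike counts must be non-negative")
    gap = params.V_T - params.V_r
    if literal_eq14:
        return g_P * gap * delta_v * counts
    if dt <= 0:
        raise ValueError("dt must be positive")
    return params.C * delta_v * gap * counts / dt
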