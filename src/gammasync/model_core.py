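"""Adaptive exponential integrate-and-fire (AdEx) neurons with conductance synapses.

Units follow the usual AdEx convention: voltages in mV, conductances in nS,
currents in pA, capacitance in pF, time in ms.  With these units
``nS * mV = pA`` and ``pA / pF = mV/ms``, so no unit conversion factors appear
in the dynamics.

The membrane equation is

    C dV/dt = I_ion(V, w) + I_AMPA + I_GABA + I_ext
    I_ion   = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_T)/Delta_T) - w
    tau_w dw/dt = a (V - E_w) - w

A spike is registered when V crosses the numerical cutoff ``V_peak``; the
voltage is then reset to ``V_r`` and clamped there for ``tau_ref`` ms, and the
adaptation current receives the increment ``b``.

Synapses are conductance based: each presynaptic spike instantaneously raises
the receptor conductance of its targets by the coupling strength J, and the
conductance decays exponentially with the receptor time constant.  The decay
is applied in exact exponential form (multiplication by ``exp(-dt/tau)``), so
conductance trajectories are independent of the step subdivision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AdExParams",
    "SynapseParams",
    "CouplingStrengths",
    "PopulationState",
    "EXCITATORY_ADEX",
    "INHIBITORY_ADEX",
    "DEFAULT_SYNAPSE",
    "DEFAULT_COUPLING",
    "adex_derivatives",
    "synaptic_currents",
    "decay_conductances",
    "apply_presynaptic_spikes",
    "threshold_reset",
]

# Argument cap for the exponential spike-initiation term.  The term only has
# to diverge fast enough to carry V across V_peak within a step; capping the
# argument prevents float overflow in predictor stages that overshoot V_peak.
_EXP_ARG_CAP = 30.0


@dataclass(frozen=True)
class AdExParams:
    """AdEx single-neuron parameters.

    Defaults are the fast-spiking interneuron values (no adaptation); see
    :data:`EXCITATORY_ADEX` for the regular-spiking pyramidal-cell set.
    ``V_peak`` is the numerical spike cutoff, not a biophysical quantity:
    spike timing is insensitive to its exact value once it sits well above
    V_T + Delta_T.  ``tau_w`` only matters when a or b are nonzero.
    """

    C: float = 200.0          # membrane capacitance, pF
    g_L: float = 10.0         # leak conductance, nS
    E_L: float = -65.0        # leak reversal, mV
    E_w: float = -80.0        # adaptation reversal, mV
    V_T: float = -50.0        # threshold, mV
    Delta_T: float = 1.5      # threshold slope factor, mV
    V_r: float = -70.0        # reset voltage, mV
    tau_ref: float = 1.0      # refractory period, ms
    a: float = 0.0            # subthreshold adaptation, nS
    b: float = 0.0            # spike-triggered adaptation, pA
    tau_w: float = 144.0      # adaptation time constant, ms
    V_peak: float = 0.0       # numerical spike cutoff, mV

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.g_L <= 0:
            raise ValueError("g_L must be positive")
        if self.Delta_T <= 0:
            raise ValueError("Delta_T must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")
        if self.V_peak <= self.V_T:
            raise ValueError("V_peak must exceed V_T")
        if self.V_r >= self.V_T:
            raise ValueError("V_r must lie below V_T")


#: Regular-spiking excitatory (pyramidal) cell: subthreshold and
#: spike-triggered adaptation switched on.
EXCITATORY_ADEX = AdExParams(a=4.0, b=40.0)

#: Fast-spiking inhibitory cell: no adaptation (a = b = 0).
INHIBITORY_ADEX = AdExParams(a=0.0, b=0.0)


@dataclass(frozen=True)
class SynapseParams:
    """Receptor time constants and reversal potentials."""

    tau_AMPA: float = 3.0     # ms
    E_AMPA: float = 0.0       # mV
    tau_GABA: float = 6.0     # ms
    E_GABA: float = -70.0     # mV

    def __post_init__(self) -> None:
        if self.tau_AMPA <= 0 or self.tau_GABA <= 0:
            raise ValueError("synaptic time constants must be positive")


DEFAULT_SYNAPSE = SynapseParams()


@dataclass(frozen=True)
class CouplingStrengths:
    """Synaptic coupling strengths (nS), within and across networks.

    ``J_ppii`` couples the two purely inhibitory networks (ING scenario);
    ``J_ppee``/``J_ppei`` couple the excitatory-inhibitory networks (PING
    scenarios).  The default across-network I-to-I strength is 0 because that
    projection only exists in the ING setup, where its strength is the swept
    state parameter.
    """

    J_etoe: float = 0.01
    J_etoi: float = 0.05
    J_itoi: float = 0.7
    J_itoe: float = 0.5
    J_ppee: float = 0.01
    J_ppei: float = 0.03
    J_ppii: float = 0.0

    def __post_init__(self) -> None:
        for name in ("J_etoe", "J_etoi", "J_itoi", "J_itoe",
                     "J_ppee", "J_ppei", "J_ppii"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


DEFAULT_COUPLING = CouplingStrengths()


@dataclass
class PopulationState:
    """Dynamic variables of one population (arrays of equal length)."""

    V: np.ndarray                    # mV
    w: np.ndarray                    # pA
    g_AMPA: np.ndarray               # nS
    g_GABA: np.ndarray               # nS
    refractory_remaining: np.ndarray  # ms

    @classmethod
    def zeros(cls, n: int, V0: float = -65.0) -> "PopulationState":
        return cls(
            V=np.full(n, float(V0)),
            w=np.zeros(n),
            g_AMPA=np.zeros(n),
            g_GABA=np.zeros(n),
            refractory_remaining=np.zeros(n),
        )

    @property
    def n(self) -> int:
        return self.V.shape[0]

    def copy(self) -> "PopulationState":
        return PopulationState(self.V.copy(), self.w.copy(), self.g_AMPA.copy(),
                               self.g_GABA.copy(), self.refractory_remaining.copy())

    def validate(self) -> None:
        n = self.V.shape[0]
        for name in ("w", "g_AMPA", "g_GABA", "refractory_remaining"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"state array {name} has inconsistent length")
        _check_finite(self.V, "V")
        _check_finite(self.w, "w")
        if np.any(self.g_AMPA < 0) or np.any(self.g_GABA < 0):
            raise ValueError("conductances must be non-negative")
        if np.any(self.refractory_remaining < 0):
            raise ValueError("refractory clocks must be non-negative")


def _check_finite(x: np.ndarray, name: str) -> None:
    bad = ~np.isfinite(x)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise FloatingPointError(
            f"non-finite value in {name} at neuron index {idx}: {x[idx]!r}")


def ionic_current(V: np.ndarray, w: np.ndarray, p: AdExParams) -> np.ndarray:
    """Intrinsic membrane current I_ion(V, w) in pA (leak + exponential - w)."""
    arg = np.minimum((V - p.V_T) / p.Delta_T, _EXP_ARG_CAP)
    return -p.g_L * (V - p.E_L) + p.g_L * p.Delta_T * np.exp(arg) - w


def adex_derivatives(
    state: PopulationState,
    params: AdExParams,
    I_syn: np.ndarray | float = 0.0,
    I_ext: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dV/dt in mV/ms, dw/dt in pA/ms) of the AdEx system.

    ``I_syn`` is the total synaptic current (AMPA + GABA) and ``I_ext`` the
    external noise drive, both in pA per neuron.
    """
    _check_finite(state.V, "V")
    _check_finite(state.w, "w")
    dV = (ionic_current(state.V, state.w, params) + I_syn + I_ext) / params.C
    dw = (params.a * (state.V - params.E_w) - state.w) / params.tau_w
    return dV, dw


def synaptic_currents(
    state: PopulationState, params: SynapseParams
) -> tuple[np.ndarray, np.ndarray]:
    """Conductance-based receptor currents (I_AMPA, I_GABA) in pA."""
    _check_finite(state.V, "V")
    I_AMPA = state.g_AMPA * (params.E_AMPA - state.V)
    I_GABA = state.g_GABA * (params.E_GABA - state.V)
    return I_AMPA, I_GABA


def decay_conductances(
    state: PopulationState, params: SynapseParams, dt: float
) -> PopulationState:
    """Decay both receptor conductances by the exact exponential factor.

    Mutates ``state`` in place and returns it.  Because the update is the
    exact solution of dg/dt = -g/tau, composing two half steps equals one
    full step for any dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.g_AMPA *= np.exp(-dt / params.tau_AMPA)
    state.g_GABA *= np.exp(-dt / params.tau_GABA)
    return state


def apply_presynaptic_spikes(
    state: PopulationState,
    spike_counts: np.ndarray | float,
    J: float,
    receptor: str,
) -> PopulationState:
    """Instantaneous conductance rise: target conductance += J * spike count.

    ``spike_counts`` is the number of presynaptic spikes arriving at each
    target neuron this step (linear superposition of simultaneous spikes).
    ``receptor`` routes the increment: "AMPA" for excitatory sources, "GABA"
    for inhibitory ones.
    """
    if J < 0:
        raise ValueError("coupling strength J must be non-negative")
    counts = np.asarray(spike_counts)
    if np.any(counts < 0):
        raise ValueError("spike counts must be non-negative")
    if receptor == "AMPA":
        state.g_AMPA += J * counts
    elif receptor == "GABA":
        state.g_GABA += J * counts
    else:
        raise ValueError(f"unknown receptor {receptor!r}; expected 'AMPA' or 'GABA'")
    return state


def threshold_reset(
    state: PopulationState, params: AdExParams, dt: float
) -> tuple[PopulationState, np.ndarray]:
    """Spike detection, reset, adaptation increment and refractory clamping.

    Neurons at or above ``V_peak`` spike: V -> V_r, w += b, and the
    refractory clock is armed at tau_ref.  Neurons already inside their
    refractory period are held at V_r (only V is clamped; w and the
    conductances keep evolving) and their clock is decremented by dt.
    """
    refractory = state.refractory_remaining > 0
    spiked = (state.V >= params.V_peak) & ~refractory
    state.V[refractory] = params.V_r
    state.refractory_remaining[refractory] -= dt
    np.maximum(state.refractory_remaining, 0.0, out=state.refractory_remaining)
    if spiked.any():
        state.V[spiked] = params.V_r
        state.w[spiked] += params.b
        state.refractory_remaining[spiked] = params.tau_ref
    return state, spiked
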