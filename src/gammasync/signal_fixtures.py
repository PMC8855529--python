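"""Synthetic signals and spike trains with known synchronization structure.

These fixtures exercise every stage of the measures pipeline (filtering,
phase extraction, R, K, frequency ratio, ISI statistics) independently of
the network simulator: each generator returns its analytic expectation
alongside the data, and the pipeline is required to reproduce it.

Available kinds:

* ``constant_lag_pair`` — two tones at one frequency with a fixed phase lag
  (expected R = 1, r = 1);
* ``drifting_pair`` — tones at f and f + drift, so the phase difference
  drifts through the circle (expected r = f/(f+drift), R near 0 once
  drift x duration >> 1);
* ``independent_pair`` — two independent band-passed white-noise signals
  (R near the finite-sample chance level);
* ``multi_neuron_coherent`` — one shared tone plus independent amplitude
  noise per neuron (K near 1);
* ``multi_neuron_dispersed`` — per-neuron constant phase offsets, either
  evenly spaced on the circle (K = 0) or von Mises distributed with
  concentration kappa (K -> I1(kappa)/I0(kappa));
* ``periodic_spiketrain`` / ``poisson_spiketrain`` — regular and Poisson
  trains with closed-form ISI moments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json
import numpy as np
from scipy import signal as sps
from scipy.special import i0, i1

from .sim_engine import SpikeRecord
from .sync_measures import GAMMA_HIGH, GAMMA_LOW, NetworkSignal

__all__ = ["FixtureSpec", "make_pair", "make_population", "make_spiketrains",
           "save_fixture_signals"]

_PAIR_KINDS = {"constant_lag_pair", "drifting_pair", "independent_pair"}
_POP_KINDS = {"multi_neuron_coherent", "multi_neuron_dispersed"}
_SPIKE_KINDS = {"periodic_spiketrain", "poisson_spiketrain"}


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    frequency: float = 60.0       # Hz
    lag: float = 0.0              # radians (constant_lag_pair)
    drift: float = 0.0            # Hz offset of the second tone
    noise_amplitude: float = 0.0  # additive white noise std (signal kinds)
    duration_ms: float = 5000.0
    fs: float = 2000.0            # Hz
    n_neurons: int = 50
    kappa: float | None = None    # von Mises concentration (dispersed kind)
    rate: float = 50.0            # Hz (spike-train kinds)
    seed: int = 0

    def __post_init__(self) -> None:
        known = _PAIR_KINDS | _POP_KINDS | _SPIKE_KINDS
        if self.kind not in known:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        in_band = self.kind in (_PAIR_KINDS | _POP_KINDS) \
            and self.kind != "independent_pair"
        if in_band and not GAMMA_LOW < self.frequency < GAMMA_HIGH:
            raise ValueError(
                f"fixture frequency {self.frequency} Hz outside the "
                f"({GAMMA_LOW}, {GAMMA_HIGH}) Hz analysis band")


def _time(spec: FixtureSpec) -> np.ndarray:
    n = int(round(spec.duration_ms * spec.fs / 1000.0))
    return np.arange(n) / spec.fs


def make_pair(spec: FixtureSpec) -> tuple[NetworkSignal, NetworkSignal,
                                          float | None, float | None]:
    """Two network-level signals plus expected (R, r); an expectation of
    None means "near the chance baseline" rather than a sharp value."""
    if spec.kind not in _PAIR_KINDS:
        raise ValueError(f"{spec.kind!r} is not a pair fixture")
    rng = np.random.default_rng(spec.seed)
    t = _time(spec)
    if spec.kind == "constant_lag_pair":
        a = np.cos(2 * np.pi * spec.frequency * t)
        b = np.cos(2 * np.pi * spec.frequency * t - spec.lag)
        exp_R, exp_r = 1.0, 1.0
    elif spec.kind == "drifting_pair":
        f2 = spec.frequency + spec.drift
        if not GAMMA_LOW < f2 < GAMMA_HIGH:
            raise ValueError("drifted frequency leaves the analysis band")
        a = np.cos(2 * np.pi * spec.frequency * t)
        b = np.cos(2 * np.pi * f2 * t)
        exp_R = None          # ~0 once drift * duration >> 1
        exp_r = min(spec.frequency, f2) / max(spec.frequency, f2)
    else:  # independent_pair
        a = rng.standard_normal(t.shape[0])
        b = rng.standard_normal(t.shape[0])
        exp_R, exp_r = None, None
    if spec.noise_amplitude:
        a = a + spec.noise_amplitude * rng.standard_normal(a.shape)
        b = b + spec.noise_amplitude * rng.standard_normal(b.shape)
    return (NetworkSignal(a, spec.fs, "A"), NetworkSignal(b, spec.fs, "B"),
            exp_R, exp_r)


def make_population(spec: FixtureSpec) -> tuple[np.ndarray, float]:
    """Per-neuron signals (n_neurons, T) plus the expected Kuramoto K.

    Coherent: identical phase, independent amplitude noise -> K near 1.
    Dispersed: constant per-neuron phase offsets; evenly spaced offsets give
    exactly K = 0, while von Mises offsets with concentration kappa give the
    closed-form mean resultant length I1(kappa)/I0(kappa) in expectation.
    """
    if spec.kind not in _POP_KINDS:
        raise ValueError(f"{spec.kind!r} is not a population fixture")
    rng = np.random.default_rng(spec.seed)
    t = _time(spec)
    omega = 2 * np.pi * spec.frequency
    if spec.kind == "multi_neuron_coherent":
        amp = 1.0 + 0.2 * rng.standard_normal((spec.n_neurons, 1))
        sigs = amp * np.cos(omega * t)[None, :]
        expected = 1.0
    else:
        if spec.kappa is None:
            offsets = 2 * np.pi * np.arange(spec.n_neurons) / spec.n_neurons
            expected = 0.0
        else:
            offsets = rng.vonmises(0.0, spec.kappa, size=spec.n_neurons)
            expected = float(i1(spec.kappa) / i0(spec.kappa))
        sigs = np.cos(omega * t[None, :] + offsets[:, None])
    if spec.noise_amplitude:
        sigs = sigs + spec.noise_amplitude * rng.standard_normal(sigs.shape)
    return sigs, expected


def make_spiketrains(spec: FixtureSpec) -> tuple[SpikeRecord, dict]:
    """Spike trains with known ISI moments.

    Periodic trains: ISI = 1000/rate ms exactly, variance 0.  Poisson
    trains: exponential ISIs with mean 1000/rate ms and variance
    (1000/rate)^2 ms^2.  Returns the record plus the expected statistics.
    """
    if spec.kind not in _SPIKE_KINDS:
        raise ValueError(f"{spec.kind!r} is not a spike-train fixture")
    rng = np.random.default_rng(spec.seed)
    period = 1000.0 / spec.rate
    ids, ts = [], []
    for j in range(spec.n_neurons):
        if spec.kind == "periodic_spiketrain":
            times = np.arange(period, spec.duration_ms, period)
        else:
            isis = rng.exponential(period,
                                   size=int(spec.duration_ms / period * 3) + 10)
            times = np.cumsum(isis)
            times = times[times < spec.duration_ms]
        ids.append(np.full(times.shape[0], j, dtype=np.int64))
        ts.append(times)
    ids = np.concatenate(ids) if ids else np.empty(0, dtype=np.int64)
    ts = np.concatenate(ts) if ts else np.empty(0)
    order = np.argsort(ts, kind="stable")
    rec = SpikeRecord(ids[order], ts[order], spec.n_neurons, spec.duration_ms)
    expected = {
        "isi_mean": period,
        "isi_var": 0.0 if spec.kind == "periodic_spiketrain" else period ** 2,
    }
    return rec, expected


def save_fixture_signals(signals: dict[str, np.ndarray], fs: float,
                         outdir) -> None:
    """Write fixture signals in the simulator's trace-archive layout
    (traces.npz + meta.json), so downstream tooling is format-agnostic."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(outdir / "traces.npz", **signals)
    (outdir / "meta.json").write_text(json.dumps({"fs": fs, "fixture": True}))
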