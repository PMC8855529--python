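"""Synchronization measures: LFP proxies, phase extraction, mean phase
coherence R, Kuramoto order parameter K, dominant frequencies, and ISI
statistics.

Pipeline: a network-level signal (mean membrane voltage, or summed absolute
synaptic currents) is band-pass filtered to the gamma analysis band
(second-order Butterworth, 30-120 Hz, applied forward-backward so the filter
is zero-phase), the instantaneous phase is taken from the analytic signal
(Hilbert transform, 100 ms trimmed at each edge), and then

    R = | (1/T) sum_t exp(i (phi_A(t) - phi_B(t))) |

measures between-network phase locking (R = 1 for any constant lag), while

    K = (1/T) sum_t | (1/N) sum_j exp(i phi_j(t)) |

measures within-population zero-lag coherence of the per-neuron phases
(K = 1 when all neurons share one phase at every instant, K near 0 for
dispersed phases).  R ignores constant inter-network lags; K by design does
not — which is why both are needed.

Frequency locking is quantified by r = f2/f1 with f2 <= f1, the ratio of the
two networks' dominant frequencies (Welch periodogram argmax); r = 1 means
1:1 entrainment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .sim_engine import SimulationResult, SpikeRecord

__all__ = [
    "NetworkSignal",
    "PhaseSeries",
    "ISIStats",
    "MeasureResult",
    "lfp_voltage_proxy",
    "lfp_current_proxy",
    "bandpass",
    "instantaneous_phase",
    "mean_phase_coherence",
    "kuramoto_order",
    "dominant_frequency",
    "frequency_ratio",
    "isi_statistics",
    "cycle_windows",
    "cycle_participation",
    "measure_run",
]

GAMMA_LOW = 30.0    # Hz, analysis band
GAMMA_HIGH = 120.0
EDGE_TRIM_MS = 100.0  # Hilbert edge transient dropped at both ends


@dataclass
class NetworkSignal:
    """Uniformly sampled scalar time series with sampling rate in Hz."""

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("NetworkSignal holds a single 1-D series")


@dataclass
class PhaseSeries:
    """Instantaneous phase (radians) over the trimmed analysis window."""

    phase: np.ndarray
    fs: float


@dataclass
class ISIStats:
    """Pooled inter-spike-interval statistics of one population."""

    mean: float           # ms; nan if no intervals
    var: float            # ms^2
    n_intervals: int
    hist: np.ndarray      # counts, 1 ms bins over [0, 100] ms
    bin_edges: np.ndarray
    empty: bool = False


@dataclass
class MeasureResult:
    """All synchronization measures of one run."""

    R: float                          # between-network mean phase coherence
    K: dict[str, float]               # Kuramoto order per population
    f: dict[int, float]               # dominant frequency per network, Hz
    r: float                          # dominant-frequency ratio in (0, 1]
    isi: dict[str, ISIStats]

    @property
    def f1(self) -> float:
        """Larger dominant frequency."""
        return max(self.f.values())

    @property
    def f2(self) -> float:
        return min(self.f.values())

    @property
    def K_mean(self) -> float:
        return float(np.mean(list(self.K.values())))


def lfp_voltage_proxy(voltage_traces: np.ndarray, fs: float,
                      label: str = "") -> NetworkSignal:
    """Mean of the per-neuron voltage traces: the network's LFP surrogate.

    ``voltage_traces`` is (n_neurons, n_samples).
    """
    traces = np.asarray(voltage_traces, dtype=float)
    if traces.ndim == 1:
        traces = traces[None, :]
    if traces.ndim != 2 or traces.shape[0] < 1:
        raise ValueError("need at least one uniformly sampled neuron trace")
    return NetworkSignal(traces.mean(axis=0), fs, label)


def lfp_current_proxy(I_AMPA: np.ndarray, I_GABA: np.ndarray, fs: float,
                      label: str = "") -> NetworkSignal:
    """Current-based LFP proxy: sum of absolute AMPA and GABA currents.

    Accepts per-neuron (2-D) traces or already-summed 1-D traces of |I|.
    """
    iA = np.asarray(I_AMPA, dtype=float)
    iG = np.asarray(I_GABA, dtype=float)
    if iA.shape != iG.shape and iA.ndim == iG.ndim == 2:
        raise ValueError("misaligned current traces")
    if iA.ndim == 2:
        iA = np.abs(iA).sum(axis=0)
        iG = np.abs(iG).sum(axis=0)
    else:
        iA, iG = np.abs(iA), np.abs(iG)
    return NetworkSignal(iA + iG, fs, label)


def bandpass(sig: NetworkSignal, low: float = GAMMA_LOW,
             high: float = GAMMA_HIGH, order: int = 2) -> NetworkSignal:
    """Zero-phase Butterworth band-pass (filter run forward then backward).

    The zero-phase application avoids the frequency-dependent lag a causal
    filter would add to every phase estimate.
    """
    if sig.fs <= 2 * high:
        raise ValueError(
            f"sampling rate {sig.fs} Hz too low for a {high} Hz highcut")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sig.fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, sig.samples - sig.samples.mean())
    return NetworkSignal(filtered, sig.fs, sig.label)


def instantaneous_phase(sig: NetworkSignal,
                        trim_ms: float = EDGE_TRIM_MS) -> PhaseSeries:
    """Phase of the analytic (Hilbert) signal, with edge transients trimmed.

    The first and last ``trim_ms`` are dropped, because the Hilbert
    transform's end effects otherwise bias downstream phase averages.
    """
    analytic = sps.hilbert(sig.samples)
    phase = np.angle(analytic)
    n_trim = int(round(trim_ms * sig.fs / 1000.0))
    if 2 * n_trim >= phase.shape[0]:
        raise ValueError("signal shorter than twice the edge trim")
    if n_trim:
        phase = phase[n_trim:-n_trim]
    return PhaseSeries(phase, sig.fs)


def mean_phase_coherence(phiA: PhaseSeries, phiB: PhaseSeries) -> float:
    """R = |mean_t exp(i (phiA - phiB))|; 1 for any constant lag."""
    a, b = phiA.phase, phiB.phase
    if a.shape != b.shape:
        raise ValueError("phase series have different lengths")
    return float(np.abs(np.mean(np.exp(1j * (a - b)))))


def kuramoto_order(phases: np.ndarray | list[PhaseSeries]) -> float:
    """Time-averaged modulus of the population-mean phasor.

    ``phases`` is (n_neurons, T) in radians (or a list of equal-length
    :class:`PhaseSeries`).  K = 1 when every neuron shares the same phase at
    every instant; evenly dispersed phases give K = 0.
    """
    if isinstance(phases, list):
        phases = np.vstack([p.phase for p in phases])
    phases = np.asarray(phases)
    if phases.ndim != 2 or phases.shape[0] < 2:
        raise ValueError("need phases of at least two neurons")
    mean_phasor = np.mean(np.exp(1j * phases), axis=0)
    return float(np.mean(np.abs(mean_phasor)))


def dominant_frequency(sig: NetworkSignal, fmin: float = 20.0,
                       fmax: float = 150.0, segment_s: float = 1.0) -> float:
    """Argmax-power frequency of the Welch periodogram, searched in
    [fmin, fmax].

    Welch settings: Hann window, ``segment_s``-second segments (1 s default,
    1 Hz resolution), 50% overlap.  The search band excludes DC and slow
    drift so the argmax reflects the oscillation.
    """
    x = sig.samples
    if not np.any(x != x.mean()):
        raise ValueError("dominant frequency undefined for a constant signal")
    nperseg = min(int(round(segment_s * sig.fs)), x.shape[0])
    freqs, psd = sps.welch(x - x.mean(), fs=sig.fs, window="hann",
                           nperseg=nperseg, noverlap=nperseg // 2)
    band = (freqs >= fmin) & (freqs <= fmax)
    if not band.any():
        raise ValueError("no Welch frequency falls inside the search band")
    fb, pb = freqs[band], psd[band]
    return float(fb[np.argmax(pb)])


def frequency_ratio(fA: float, fB: float) -> float:
    """r = min(fA, fB) / max(fA, fB) in (0, 1]; r = 1 <=> frequency locked."""
    if fA <= 0 or fB <= 0:
        raise ValueError("frequencies must be positive")
    return min(fA, fB) / max(fA, fB)


def isi_statistics(spikes: SpikeRecord, t_max: float = 100.0,
                   bin_width: float = 1.0) -> ISIStats:
    """Inter-spike intervals pooled over the neurons of one population.

    Intervals are formed per neuron and pooled; the histogram uses
    ``bin_width``-ms bins over [0, t_max] ms.  A population without any
    interval yields an explicitly flagged empty result.
    """
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    isis = []
    if spikes.n_spikes >= 2:
        order = np.lexsort((spikes.times, spikes.neuron_ids))
        ids = spikes.neuron_ids[order]
        ts = spikes.times[order]
        d = np.diff(ts)
        same = ids[1:] == ids[:-1]
        isis = d[same]
    isis = np.asarray(isis, dtype=float)
    if isis.size == 0:
        return ISIStats(np.nan, np.nan, 0, np.zeros(len(edges) - 1), edges,
                        empty=True)
    hist, _ = np.histogram(isis, bins=edges)
    return ISIStats(float(isis.mean()), float(isis.var()), int(isis.size),
                    hist, edges)


def cycle_windows(sig: NetworkSignal, fmin: float = GAMMA_LOW) -> np.ndarray:
    """Gamma-cycle windows from the peaks of a (band-passed) reference
    signal.

    Returns an (n_cycles, 2) array of [t_start, t_end] in ms: each window is
    bounded by the midpoints between consecutive oscillation peaks, so one
    window covers one cycle of the reference rhythm.
    """
    min_dist = max(1, int(round(sig.fs / 150.0)))
    peaks, _ = sps.find_peaks(sig.samples, distance=min_dist,
                              prominence=np.std(sig.samples) * 0.5)
    if peaks.size < 3:
        raise ValueError("too few oscillation peaks to define cycles")
    t = peaks * 1000.0 / sig.fs
    mids = (t[:-1] + t[1:]) / 2.0
    return np.column_stack([mids[:-1], mids[1:]])


def cycle_participation(spikes: SpikeRecord,
                        windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle participation of a population in reference cycles.

    For each window the fraction of neurons that spike at least once inside
    it, plus the (n_neurons, n_cycles) boolean participation matrix from
    which skip patterns (participation in consecutive cycles c_{i-1}, c_i,
    c_{i+1}) can be read off.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2 or windows.shape[0] == 0:
        raise ValueError("no reference cycles supplied")
    n_cycles = windows.shape[0]
    participated = np.zeros((spikes.n_neurons, n_cycles), dtype=bool)
    if spikes.n_spikes:
        starts = windows[:, 0]
        idx = np.searchsorted(starts, spikes.times, side="right") - 1
        ok = (idx >= 0) & (spikes.times <= windows[np.clip(idx, 0, None), 1])
        participated[spikes.neuron_ids[ok], idx[ok]] = True
    fractions = participated.mean(axis=0)
    return fractions, participated


def _phases_2d(traces: np.ndarray, fs: float,
               trim_ms: float = EDGE_TRIM_MS) -> np.ndarray:
    """Band-pass + Hilbert phase of many traces at once: (n, T) -> (n, T')."""
    sos = sps.butter(2, [GAMMA_LOW, GAMMA_HIGH], btype="bandpass", fs=fs,
                     output="sos")
    centered = traces - traces.mean(axis=1, keepdims=True)
    filtered = sps.sosfiltfilt(sos, centered, axis=1)
    phase = np.angle(sps.hilbert(filtered, axis=1))
    n_trim = int(round(trim_ms * fs / 1000.0))
    return phase[:, n_trim:-n_trim] if n_trim else phase


def _network_phase(result: SimulationResult, network: int, discard: int,
                   proxy: str) -> tuple[PhaseSeries, NetworkSignal]:
    if proxy == "voltage":
        raw = result.network_mean_voltage(network)[discard:]
    elif proxy == "current":
        iA, iG = result.network_abs_current(network)
        raw = (iA + iG)[discard:]
    else:
        raise ValueError("proxy must be 'voltage' or 'current'")
    sig = bandpass(NetworkSignal(raw, result.fs, f"net{network}"))
    return instantaneous_phase(sig), sig


def measure_run(result: SimulationResult, proxy: str = "voltage",
                max_kuramoto_neurons: int | None = None) -> MeasureResult:
    """Full measures pipeline on one simulation result.

    Discards the configured transient, computes the between-network mean
    phase coherence R on the chosen LFP proxy, the Kuramoto order parameter
    per population from the recorded per-neuron voltage traces (all recorded
    neurons by default; ``max_kuramoto_neurons`` subsamples them), dominant
    frequencies and their ratio, and pooled ISI statistics per population.
    """
    discard = int(round(result.config.transient_discard * result.fs / 1000.0))
    phases = {}
    sigs = {}
    for net in (1, 2):
        phases[net], sigs[net] = _network_phase(result, net, discard, proxy)
    R = mean_phase_coherence(phases[1], phases[2])
    f = {net: dominant_frequency(sigs[net]) for net in (1, 2)}
    r = frequency_ratio(f[1], f[2])

    K = {}
    for p in result.spec.populations:
        V = result.traces[p.pid].V[:, discard:]
        if max_kuramoto_neurons is not None and V.shape[0] > max_kuramoto_neurons:
            V = V[:max_kuramoto_neurons]
        K[p.pid] = kuramoto_order(_phases_2d(V, result.fs))

    t0 = result.config.transient_discard
    isi = {}
    for p in result.spec.populations:
        rec = result.spikes[p.pid]
        keep = rec.times >= t0
        isi[p.pid] = isi_statistics(
            SpikeRecord(rec.neuron_ids[keep], rec.times[keep], rec.n_neurons,
                        rec.duration))
    return MeasureResult(R=R, K=K, f=f, r=r, isi=isi)
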