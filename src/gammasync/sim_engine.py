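"""Fixed-step integration of the full two-network system.

Per-step order of operations:

1. decay all synaptic conductances (exact exponential update);
2. draw per-neuron Poisson noise counts and form the external current;
3. integrate V and w one step (Heun predictor-corrector on the
   deterministic drift by default; forward Euler available);
4. detect threshold crossings, reset, arm refractory clocks;
5. deliver this step's spikes to their targets (conductance increments),
   honoring the projection delay (delay 0 = delivery within the same step,
   i.e. an effective latency of at most one step).

Voltage-dependent synaptic currents are evaluated inside the integrator
(conductances held fixed over the step), so the Heun corrector sees the
driving-force change of the predictor voltage.  Because the external noise
enters as discrete per-step spike counts rather than a continuous diffusion,
the stochastic Heun scheme degenerates to deterministic Heun here.

For speed, all populations are flattened into one global state vector with
per-neuron parameter arrays, and all same-receptor zero-delay sparse
projections are merged into a single weighted CSR edge structure, so spike
delivery is one gather + bincount per receptor per step.  All-to-all
projections use an O(N) counting shortcut.

Seeding: one master seed spawns independent substreams for connectivity,
initial conditions, and one noise stream per population; identical seed and
configuration give bit-identical spike rasters.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .network_build import ScenarioSpec, sample_adjacency
from .noise_drive import input_strength, network2_rate, poisson_rate

try:
    import numba as _numba
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

__all__ = [
    "SimulationConfig",
    "SpikeRecord",
    "PopulationTraces",
    "SimulationResult",
    "run",
    "save_result",
    "load_result_traces",
]

# Soft cap on recorded per-neuron voltage samples before the stride is
# automatically coarsened (memory guard).
_RECORD_SAMPLE_CAP = 50_000_000

# Argument cap for the exponential spike-initiation term (overflow guard;
# the neuron is reset at V_peak anyway).
_EXP_CAP = 30.0


@dataclass(frozen=True)
class SimulationConfig:
    """Run settings.

    ``record_stride`` is in integration steps; the default (None) targets a
    2 kHz trace sampling (one sample per 0.5 ms), ample for a 30-120 Hz
    analysis band.  ``n_record_neurons`` bounds the per-neuron voltage
    recording per population (None records every neuron); the recorded
    subset is a seeded choice.  ``transient_discard`` is metadata consumed
    by the measures pipeline, which drops that initial stretch before any
    statistic.
    """

    dt: float = 0.05                 # ms
    duration: float = 5000.0         # ms
    integrator: str = "heun"         # "heun" | "euler"
    record_stride: int | None = None
    n_record_neurons: int | None = 128
    transient_discard: float = 500.0  # ms
    seed: int | None = None
    literal_eq14: bool = False
    accelerated: bool = True         # use the compiled kernel when available

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.transient_discard < 0:
            raise ValueError("transient_discard must be non-negative")
        if self.duration > 0 and self.duration <= self.transient_discard:
            raise ValueError("duration must exceed transient_discard")
        if self.integrator not in ("heun", "euler"):
            raise ValueError("integrator must be 'heun' or 'euler'")


@dataclass
class SpikeRecord:
    """Event log of one population: parallel arrays of neuron index and
    spike time (ms), in time order."""

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float

    @property
    def n_spikes(self) -> int:
        return int(self.times.shape[0])

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.times[self.neuron_ids == neuron]


@dataclass
class PopulationTraces:
    """Uniformly sampled recordings of one population."""

    mean_V: np.ndarray               # mV, population mean over ALL neurons
    V: np.ndarray                    # mV, (n_recorded, n_samples)
    record_ids: np.ndarray           # neuron indices of the rows of V
    sum_abs_I_AMPA: np.ndarray       # pA, summed |I_AMPA| over all neurons
    sum_abs_I_GABA: np.ndarray       # pA


@dataclass
class SimulationResult:
    spec: ScenarioSpec
    config: SimulationConfig
    time: np.ndarray                 # ms, sample times
    fs: float                        # Hz, trace sampling rate
    spikes: dict[str, SpikeRecord]
    traces: dict[str, PopulationTraces]

    def network_mean_voltage(self, network: int) -> np.ndarray:
        """LFP proxy: average membrane voltage over all neurons of a network."""
        pops = [p for p in self.spec.populations if p.network == network]
        if not pops:
            raise ValueError(f"no populations in network {network}")
        total = sum(p.n for p in pops)
        acc = np.zeros_like(self.traces[pops[0].pid].mean_V)
        for p in pops:
            acc += p.n * self.traces[p.pid].mean_V
        return acc / total

    def network_abs_current(self, network: int) -> tuple[np.ndarray, np.ndarray]:
        """Summed |I_AMPA| and |I_GABA| over all neurons of a network."""
        pops = [p for p in self.spec.populations if p.network == network]
        iA = sum(self.traces[p.pid].sum_abs_I_AMPA for p in pops)
        iG = sum(self.traces[p.pid].sum_abs_I_GABA for p in pops)
        return iA, iG


def _gather_counts(idx: np.ndarray, indptr: np.ndarray, indices: np.ndarray,
                   weights: np.ndarray, n_total: int) -> np.ndarray:
    """Weighted in-degree of each target from the spiking sources ``idx``.

    Vectorized concatenation of the CSR ranges of all spiking sources,
    followed by a weighted bincount over targets.
    """
    starts = indptr[idx]
    lens = indptr[idx + 1] - starts
    total = int(lens.sum())
    if total == 0:
        return None
    cum = np.cumsum(lens)
    flat = np.arange(total) + np.repeat(starts - (cum - lens), lens)
    return np.bincount(indices[flat], weights=weights[flat],
                       minlength=n_total)


def _sim_chunk(V, w, gA, gG, refr, refr_mask, counts, ext_factor,
               decay_A, decay_G, dt, heun, E_A, E_G,
               C_, gL_, EL_, Ew_, VT_, DT_, Vr_, tref_, a_, b_, tw_, Vpk_,
               dense_meta, dense_J,
               iptrA, indA, wA, iptrG, indG, wG,
               stride, step0, snapV, snapA, snapG,
               sp_idx, sp_step):
    """One chunk of the step loop, written element-wise for JIT compilation.

    Arithmetic mirrors the vectorized reference loop operation for
    operation, so both paths produce the same trajectories.  Returns
    (number of spikes written, error step or -1, snapshots written).
    """
    n = V.shape[0]
    n_chunk = counts.shape[0]
    n_dense = dense_meta.shape[0]
    nsp = 0
    snap_i = 0
    for s in range(n_chunk):
        for i in range(n):
            gA[i] *= decay_A
            gG[i] *= decay_G
            refr_mask[i] = refr[i] > 0.0
        # integrate V, w (conductances fixed over the step)
        for i in range(n):
            I_ext = ext_factor[i] * counts[s, i]
            arg = (V[i] - VT_[i]) / DT_[i]
            if arg > _EXP_CAP:
                arg = _EXP_CAP
            I_ion = -gL_[i] * (V[i] - EL_[i]) + gL_[i] * DT_[i] * np.exp(arg) - w[i]
            I_syn = gA[i] * (E_A - V[i]) + gG[i] * (E_G - V[i])
            f1V = (I_ion + I_syn + I_ext) / C_[i]
            f1w = (a_[i] * (V[i] - Ew_[i]) - w[i]) / tw_[i]
            if heun:
                V1 = V[i] + dt * f1V
                w1 = w[i] + dt * f1w
                if V1 > Vpk_[i]:
                    V1 = Vpk_[i]
                if refr_mask[i]:
                    V1 = Vr_[i]
                arg = (V1 - VT_[i]) / DT_[i]
                if arg > _EXP_CAP:
                    arg = _EXP_CAP
                I_ion = -gL_[i] * (V1 - EL_[i]) + gL_[i] * DT_[i] * np.exp(arg) - w1
                I_syn = gA[i] * (E_A - V1) + gG[i] * (E_G - V1)
                f2V = (I_ion + I_syn + I_ext) / C_[i]
                f2w = (a_[i] * (V1 - Ew_[i]) - w1) / tw_[i]
                V[i] = V[i] + 0.5 * dt * (f1V + f2V)
                w[i] = w[i] + 0.5 * dt * (f1w + f2w)
            else:
                V[i] = V[i] + dt * f1V
                w[i] = w[i] + dt * f1w
            if refr_mask[i]:
                V[i] = Vr_[i]
        # threshold, reset, refractory
        sp_start = nsp
        for i in range(n):
            if not np.isfinite(V[i]):
                return nsp, step0 + s, snap_i
            if V[i] >= Vpk_[i] and not refr_mask[i]:
                sp_idx[nsp] = i
                sp_step[nsp] = s
                nsp += 1
                V[i] = Vr_[i]
                w[i] += b_[i]
                refr[i] = tref_[i]
            if refr_mask[i]:
                refr[i] -= dt
                if refr[i] < 0.0:
                    refr[i] = 0.0
        # spike delivery: dense (all-to-all) projections by counting,
        # sparse merged CSR edges by scatter
        for dp in range(n_dense):
            slo = dense_meta[dp, 0]
            shi = dense_meta[dp, 1]
            tlo = dense_meta[dp, 2]
            thi = dense_meta[dp, 3]
            flags = dense_meta[dp, 4]
            cnt = 0
            for q in range(sp_start, nsp):
                if slo <= sp_idx[q] < shi:
                    cnt += 1
            if cnt:
                J = dense_J[dp]
                g = gA if flags & 2 else gG
                add = J * cnt
                for t in range(tlo, thi):
                    g[t] += add
                if flags & 1:  # recurrent: no autapse contribution
                    for q in range(sp_start, nsp):
                        if slo <= sp_idx[q] < shi:
                            g[sp_idx[q]] -= J
        for q in range(sp_start, nsp):
            i = sp_idx[q]
            for e in range(iptrA[i], iptrA[i + 1]):
                gA[indA[e]] += wA[e]
            for e in range(iptrG[i], iptrG[i + 1]):
                gG[indG[e]] += wG[e]
        # trace snapshots
        if stride > 0 and (step0 + s + 1) % stride == 0:
            for i in range(n):
                snapV[snap_i, i] = V[i]
                snapA[snap_i, i] = gA[i]
                snapG[snap_i, i] = gG[i]
            snap_i += 1
    return nsp, -1, snap_i


_compiled_chunk = None


def _get_chunk_kernel():
    global _compiled_chunk
    if _compiled_chunk is None:
        _compiled_chunk = _numba.njit(cache=True, fastmath=False)(_sim_chunk)
    return _compiled_chunk


def run(spec: ScenarioSpec, config: SimulationConfig | None = None) -> SimulationResult:
    """Simulate a scenario and return the full recording.

    If ``config`` is omitted it is derived from the spec's duration/dt/seed.
    A ``config`` with ``seed=None`` also falls back to the spec's seed.
    """
    if config is None:
        config = SimulationConfig(dt=spec.dt, duration=spec.duration, seed=spec.seed)
    seed = spec.seed if config.seed is None else config.seed
    dt = config.dt
    n_steps = int(round(config.duration / dt))

    pops = list(spec.populations)
    sizes = {p.pid: p.n for p in pops}
    offsets = {}
    off = 0
    for p in pops:
        offsets[p.pid] = off
        off += p.n
    n_total = off
    syn = spec.synapse

    ss = np.random.SeedSequence(seed)
    conn_ss, init_ss, *noise_ss = ss.spawn(2 + len(pops))
    conn_rng = np.random.default_rng(conn_ss)
    init_rng = np.random.default_rng(init_ss)
    noise_rngs = [np.random.default_rng(s) for s in noise_ss]

    # Per-neuron parameter vectors (populations may differ, e.g. adaptation).
    def par(name):
        return np.concatenate([np.full(p.n, getattr(p.adex, name))
                               for p in pops])

    C_, gL_, EL_, Ew_, VT_, DT_, Vr_, tref_, a_, b_, tw_, Vpk_ = (
        par(n) for n in ("C", "g_L", "E_L", "E_w", "V_T", "Delta_T", "V_r",
                         "tau_ref", "a", "b", "tau_w", "V_peak"))
    E_A, E_G = syn.E_AMPA, syn.E_GABA

    # Connectivity, sampled in fixed projection order for reproducibility.
    # Zero-delay sparse projections are merged per receptor into one global
    # weighted CSR; dense (all-to-all) and delayed projections stay separate.
    dense_projs = []        # (src_pid, tgt_pid, J, receptor, d, ring)
    sparse_edges = {}       # (receptor, d) -> [(src_gl, tgt_gl, w), ...]
    adjacency = {}
    for proj in spec.projections:
        adj = sample_adjacency(proj, sizes, conn_rng)
        adjacency[(proj.source, proj.target)] = adj
        d = int(round(proj.delay / dt))
        if adj.dense:
            ring = np.zeros((d + 1, sizes[proj.target])) if d > 0 else None
            dense_projs.append((proj.source, proj.target, proj.strength,
                                proj.receptor, d, ring))
        else:
            src, tgt = adj.pairs()
            sparse_edges.setdefault((proj.receptor, d), []).append(
                (src + offsets[proj.source], tgt + offsets[proj.target],
                 proj.strength))
    sparse_groups = []      # (receptor, d, indptr, indices, weights, ring)
    for (receptor, d), parts in sparse_edges.items():
        src = np.concatenate([p[0] for p in parts])
        tgt = np.concatenate([p[1] for p in parts])
        wts = np.concatenate([np.full(p[0].shape[0], p[2]) for p in parts])
        order = np.argsort(src, kind="stable")
        src, tgt, wts = src[order], tgt[order], wts[order]
        indptr = np.zeros(n_total + 1, dtype=np.int64)
        np.cumsum(np.bincount(src, minlength=n_total), out=indptr[1:])
        ring = np.zeros((d + 1, n_total)) if d > 0 else None
        sparse_groups.append((receptor, d, indptr, tgt.astype(np.int64),
                              wts, ring))

    # Per-population noise settings.
    lam1 = poisson_rate(spec.noise.mu_v, spec.noise.sigma2, spec.noise.N_p)
    lam2 = network2_rate(lam1, spec.noise.p_ratio)
    delta_v = input_strength(spec.noise.sigma2, spec.noise.mu_v)
    noise_mean = []
    for p in pops:
        lam = (lam1 if p.network == 1 else lam2) * p.noise_rate_factor
        noise_mean.append(spec.noise.N_p * lam * dt / 1000.0)
    gap_ = VT_ - Vr_
    if config.literal_eq14:
        ext_factor = spec.noise.g_P * gap_ * delta_v
    else:
        ext_factor = C_ * delta_v * gap_ / dt

    # Initial conditions: desynchronized start, V uniform in [E_L, V_T].
    V = init_rng.uniform(EL_, VT_)
    w = np.zeros(n_total)
    gA = np.zeros(n_total)
    gG = np.zeros(n_total)
    refr = np.zeros(n_total)

    # Recording setup.
    stride = config.record_stride or max(1, int(round(0.5 / dt)))
    n_rec_per_pop = [p.n if config.n_record_neurons is None
                     else min(config.n_record_neurons, p.n) for p in pops]
    n_samples = n_steps // stride if n_steps else 0
    total = sum(n_rec_per_pop) * max(n_samples, 1)
    while total > _RECORD_SAMPLE_CAP:
        stride *= 2
        n_samples = n_steps // stride
        total = sum(n_rec_per_pop) * max(n_samples, 1)
        warnings.warn("voltage recording too large; record stride increased "
                      f"to {stride} steps")
    record_ids = [np.sort(init_rng.choice(p.n, size=nr, replace=False))
                  for p, nr in zip(pops, n_rec_per_pop)]
    record_ids_gl = [ids + offsets[p.pid]
                     for p, ids in zip(pops, record_ids)]
    pop_slices = [slice(offsets[p.pid], offsets[p.pid] + p.n) for p in pops]

    mean_V = [np.empty(n_samples) for _ in pops]
    V_rec = [np.empty((nr, n_samples)) for nr in n_rec_per_pop]
    iA_rec = [np.empty(n_samples) for _ in pops]
    iG_rec = [np.empty(n_samples) for _ in pops]
    sample_t = np.empty(n_samples)
    spike_idx_chunks = []
    spike_t_chunks = []

    decay_A = np.exp(-dt / syn.tau_AMPA)
    decay_G = np.exp(-dt / syn.tau_GABA)
    heun = config.integrator == "heun"
    counts = np.zeros(n_total)
    boundaries = np.array([offsets[p.pid] for p in pops] + [n_total])

    def drift(V_, w_, I_ext):
        arg = np.minimum((V_ - VT_) / DT_, _EXP_CAP)
        I_ion = -gL_ * (V_ - EL_) + gL_ * DT_ * np.exp(arg) - w_
        I_syn = gA * (E_A - V_) + gG * (E_G - V_)
        return (I_ion + I_syn + I_ext) / C_, (a_ * (V_ - Ew_) - w_) / tw_

    # Dispatch: compiled chunked kernel when numba is available and no
    # projection carries a delay (the study's configurations all use zero
    # delay); otherwise the vectorized reference loop below.
    use_fast = (config.accelerated and _HAVE_NUMBA and n_steps > 0
                and all(dp[4] == 0 for dp in dense_projs)
                and all(g[1] == 0 for g in sparse_groups))
    sample_idx = 0
    if use_fast:
        dense_meta = np.zeros((len(dense_projs), 5), dtype=np.int64)
        dense_J_arr = np.zeros(len(dense_projs))
        for j, (spid, tpid, J, receptor, d, _ring) in enumerate(dense_projs):
            dense_meta[j] = (offsets[spid], offsets[spid] + sizes[spid],
                             offsets[tpid], offsets[tpid] + sizes[tpid],
                             (2 if receptor == "AMPA" else 0)
                             | (1 if spid == tpid else 0))
            dense_J_arr[j] = J
        empty_ptr = np.zeros(n_total + 1, dtype=np.int64)
        empty_idx = np.empty(0, dtype=np.int64)
        empty_w = np.empty(0)
        iptrA, indA, wts_A = empty_ptr, empty_idx, empty_w
        iptrG, indG, wts_G = empty_ptr, empty_idx, empty_w
        for receptor, d, indptr, indices, wts, _ring in sparse_groups:
            if receptor == "AMPA":
                iptrA, indA, wts_A = indptr, indices, wts
            else:
                iptrG, indG, wts_G = indptr, indices, wts
        kernel = _get_chunk_kernel()
        chunk = 512
        refr_mask_buf = np.zeros(n_total, dtype=np.bool_)
        sp_idx_buf = np.empty(chunk * n_total, dtype=np.int64)
        sp_step_buf = np.empty(chunk * n_total, dtype=np.int64)
        counts2d = np.zeros((chunk, n_total))
        max_snap = chunk // stride + 2
        snapV = np.empty((max_snap, n_total))
        snapA = np.empty((max_snap, n_total))
        snapG = np.empty((max_snap, n_total))
        step0 = 0
        while step0 < n_steps:
            nc = min(chunk, n_steps - step0)
            cc = counts2d[:nc]
            for k, sl in enumerate(pop_slices):
                if noise_mean[k] > 0:
                    cc[:, sl] = noise_rngs[k].poisson(
                        noise_mean[k], size=(nc, sl.stop - sl.start))
            nsp, err, nsnap = kernel(
                V, w, gA, gG, refr, refr_mask_buf, cc, ext_factor,
                decay_A, decay_G, dt, heun, E_A, E_G,
                C_, gL_, EL_, Ew_, VT_, DT_, Vr_, tref_, a_, b_, tw_, Vpk_,
                dense_meta, dense_J_arr,
                iptrA, indA, wts_A, iptrG, indG, wts_G,
                stride if n_samples else 0, step0,
                snapV, snapA, snapG, sp_idx_buf, sp_step_buf)
            if err >= 0:
                raise FloatingPointError(f"numerical blow-up at step {err}")
            if nsp:
                spike_idx_chunks.append(sp_idx_buf[:nsp].copy())
                spike_t_chunks.append((step0 + sp_step_buf[:nsp] + 1) * dt)
            if nsnap:
                rows = snapV[:nsnap]
                absA = snapA[:nsnap] * np.abs(E_A - rows)
                absG = snapG[:nsnap] * np.abs(E_G - rows)
                out = slice(sample_idx, sample_idx + nsnap)
                for k, sl in enumerate(pop_slices):
                    mean_V[k][out] = rows[:, sl].mean(axis=1)
                    V_rec[k][:, out] = rows[:, record_ids_gl[k]].T
                    iA_rec[k][out] = absA[:, sl].sum(axis=1)
                    iG_rec[k][out] = absG[:, sl].sum(axis=1)
                first = stride - 1 - (step0 % stride)
                sampled = step0 + np.arange(first, nc, stride)
                sample_t[out] = (sampled + 1) * dt
                sample_idx += nsnap
            step0 += nc
        n_steps_iter = 0
    else:
        n_steps_iter = n_steps
    for step in range(n_steps_iter):
        t_next = (step + 1) * dt
        # 1. exact conductance decay
        gA *= decay_A
        gG *= decay_G
        # 2. noise counts and external current
        for k, sl in enumerate(pop_slices):
            if noise_mean[k] > 0:
                counts[sl] = noise_rngs[k].poisson(noise_mean[k],
                                                   size=sl.stop - sl.start)
        I_ext = ext_factor * counts
        # 3. integrate V and w
        refr_mask = refr > 0.0
        f1V, f1w = drift(V, w, I_ext)
        if heun:
            V1 = V + dt * f1V
            w1 = w + dt * f1w
            # Cap the predictor at the spike cutoff: drift beyond V_peak is
            # unphysical (the neuron is reset there) and the exponential
            # blow-up would otherwise contaminate the corrector stage of w
            # through the a*(V - E_w) term.
            np.minimum(V1, Vpk_, out=V1)
            V1[refr_mask] = Vr_[refr_mask]
            f2V, f2w = drift(V1, w1, I_ext)
            V += 0.5 * dt * (f1V + f2V)
            w += 0.5 * dt * (f1w + f2w)
        else:
            V += dt * f1V
            w += dt * f1w
        V[refr_mask] = Vr_[refr_mask]
        # 4. threshold, reset, refractory
        if not np.isfinite(V).all():
            bad = int(np.flatnonzero(~np.isfinite(V))[0])
            raise FloatingPointError(
                f"numerical blow-up at neuron {bad} (global index), "
                f"step {step}")
        sp = (V >= Vpk_) & ~refr_mask
        idx = np.flatnonzero(sp)
        if idx.size:
            V[idx] = Vr_[idx]
            w[idx] += b_[idx]
            refr[idx] = tref_[idx]
            spike_idx_chunks.append(idx)
            spike_t_chunks.append(np.full(idx.size, t_next))
        refr[refr_mask] -= dt
        np.maximum(refr, 0.0, out=refr)
        # 5. spike delivery
        if dense_projs or sparse_groups:
            for src_pid, tgt_pid, J, receptor, d, ring in dense_projs:
                ssl = slice(offsets[src_pid], offsets[src_pid] + sizes[src_pid])
                tsl = slice(offsets[tgt_pid], offsets[tgt_pid] + sizes[tgt_pid])
                n_sp = int(np.count_nonzero(sp[ssl]))
                if d == 0:
                    if n_sp:
                        g = gA if receptor == "AMPA" else gG
                        g[tsl] += J * n_sp
                        if src_pid == tgt_pid:
                            g[ssl.start + np.flatnonzero(sp[ssl])] -= J
                else:
                    slot = step % (d + 1)
                    inc = ring[slot]
                    g = gA if receptor == "AMPA" else gG
                    g[tsl] += inc
                    ring[slot] = 0.0
                    if n_sp:
                        pend = ring[(step + d) % (d + 1)]
                        pend += J * n_sp
                        if src_pid == tgt_pid:
                            pend[np.flatnonzero(sp[ssl])] -= J
            for receptor, d, indptr, indices, wts, ring in sparse_groups:
                g = gA if receptor == "AMPA" else gG
                if d == 0:
                    if idx.size:
                        inc = _gather_counts(idx, indptr, indices, wts,
                                             n_total)
                        if inc is not None:
                            g += inc
                else:
                    slot = step % (d + 1)
                    g += ring[slot]
                    ring[slot] = 0.0
                    if idx.size:
                        inc = _gather_counts(idx, indptr, indices, wts,
                                             n_total)
                        if inc is not None:
                            ring[(step + d) % (d + 1)] += inc
        # recording
        if n_samples and (step + 1) % stride == 0:
            absA = gA * np.abs(E_A - V)
            absG = gG * np.abs(E_G - V)
            for k, sl in enumerate(pop_slices):
                mean_V[k][sample_idx] = V[sl].mean()
                V_rec[k][:, sample_idx] = V[record_ids_gl[k]]
                iA_rec[k][sample_idx] = absA[sl].sum()
                iG_rec[k][sample_idx] = absG[sl].sum()
            sample_t[sample_idx] = t_next
            sample_idx += 1

    # Split the global spike log into per-population records.
    if spike_idx_chunks:
        all_idx = np.concatenate(spike_idx_chunks)
        all_t = np.concatenate(spike_t_chunks)
    else:
        all_idx = np.empty(0, dtype=np.int64)
        all_t = np.empty(0)
    spikes = {}
    traces = {}
    for k, p in enumerate(pops):
        lo, hi = boundaries[k], boundaries[k + 1]
        sel = (all_idx >= lo) & (all_idx < hi)
        spikes[p.pid] = SpikeRecord(all_idx[sel] - lo, all_t[sel], p.n,
                                    config.duration)
        traces[p.pid] = PopulationTraces(
            mean_V=mean_V[k], V=V_rec[k], record_ids=record_ids[k],
            sum_abs_I_AMPA=iA_rec[k], sum_abs_I_GABA=iG_rec[k])

    fs = 1000.0 / (dt * stride)
    return SimulationResult(spec=spec, config=config, time=sample_t[:sample_idx],
                            fs=fs, spikes=spikes, traces=traces)


def _config_hash(config: SimulationConfig, spec: ScenarioSpec) -> str:
    payload = repr((asdict(config), spec.scenario, spec.noise, spec.coupling,
                    spec.duration, spec.dt, spec.seed))
    return hashlib.md5(payload.encode()).hexdigest()[:12]


def save_result(result: SimulationResult, outdir) -> None:
    """Write spikes as two-column text per population and traces as a
    compressed array archive with a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pid, rec in result.spikes.items():
        np.savetxt(outdir / f"spikes_{pid}.txt",
                   np.column_stack([rec.neuron_ids, rec.times]),
                   fmt="%d %.3f", header="neuron_id time_ms")
    arrays = {"time": result.time}
    for pid, tr in result.traces.items():
        arrays[f"meanV_{pid}"] = tr.mean_V
        arrays[f"V_{pid}"] = tr.V
        arrays[f"recorded_{pid}"] = tr.record_ids
        arrays[f"absIA_{pid}"] = tr.sum_abs_I_AMPA
        arrays[f"absIG_{pid}"] = tr.sum_abs_I_GABA
    np.savez_compressed(outdir / "traces.npz", **arrays)
    meta = {
        "dt": result.config.dt,
        "fs": result.fs,
        "duration": result.config.duration,
        "transient_discard": result.config.transient_discard,
        "scenario": result.spec.scenario,
        "populations": {p.pid: p.n for p in result.spec.populations},
        "seed": result.config.seed if result.config.seed is not None
                else result.spec.seed,
        "config_hash": _config_hash(result.config, result.spec),
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))


def load_result_traces(outdir) -> tuple[dict, dict]:
    """Load the trace archive written by :func:`save_result`; returns
    (arrays dict, metadata dict)."""
    outdir = Path(outdir)
    with np.load(outdir / "traces.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads((outdir / "meta.json").read_text())
    return arrays, meta
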