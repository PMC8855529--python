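"""Construction of the two-network scenarios.

Three experimental setups are supported:

* **Scenario 1** — two purely inhibitory networks of 1,000 cells each,
  all-to-all connected within and across networks (gamma through mutual
  inhibition, the ING mechanism).  The across-network I→I strength is the
  state parameter.
* **Scenario 2** — two excitatory-inhibitory networks (1,000 E + 250 I per
  network), all-to-all connected (PING mechanism).
* **Scenario 3** — as scenario 2 but with sparse Bernoulli-random
  connectivity at the tabulated probabilities.

Across-network communication in the EI scenarios is purely excitatory (E→E
and E→I onto the other network); long-range inhibition is absent, matching
the predominantly excitatory character of cortico-cortical projections.
Autapses are excluded everywhere.

``STATE_CONFIGS`` holds the parameter triples (p, sigma^2, J_pp**) of the
three canonical dynamical states per scenario: (1) within-synchronized but
across-unsynchronized, (2) coupling-locked, (3) noise-locked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import (
    AdExParams,
    CouplingStrengths,
    EXCITATORY_ADEX,
    INHIBITORY_ADEX,
    SynapseParams,
)
from .noise_drive import NoiseParams

__all__ = [
    "ProjectionSpec",
    "PopulationSpec",
    "ScenarioSpec",
    "Adjacency",
    "DEFAULT_PROBABILITIES",
    "STATE_CONFIGS",
    "build_scenario",
    "build_state",
    "sample_adjacency",
    "write_edge_list",
    "read_edge_list",
]

#: Connection probabilities of the sparse scenario (scenario 3).
DEFAULT_PROBABILITIES = {
    "p_etoe": 0.2,
    "p_etoi": 0.4,
    "p_itoe": 0.4,
    "p_itoi": 0.4,
    "p_ppee": 0.1,
    "p_ppei": 0.4,
}

#: Canonical state parameter triples (Poisson rate ratio, noise strength,
#: across-network coupling) for the ING scenario (1) and the sparse PING
#: scenario (3).
STATE_CONFIGS = {
    (1, 1): {"p_ratio": 0.85, "sigma2": 0.5, "J_ppii": 0.15},
    (1, 2): {"p_ratio": 0.85, "sigma2": 0.5, "J_ppii": 0.3},
    (1, 3): {"p_ratio": 0.85, "sigma2": 1.5, "J_ppii": 0.15},
    (3, 1): {"p_ratio": 0.85, "sigma2": 0.7, "J_ppei": 0.03},
    (3, 2): {"p_ratio": 0.85, "sigma2": 0.7, "J_ppei": 0.07},
    (3, 3): {"p_ratio": 0.85, "sigma2": 4.5, "J_ppei": 0.03},
}


@dataclass(frozen=True)
class PopulationSpec:
    """One population: id like "E1"/"I2", size, neuron parameters, and the
    fraction of the network's noise rate it receives."""

    pid: str
    n: int
    adex: AdExParams
    network: int              # 1 or 2
    kind: str                 # "E" or "I"
    noise_rate_factor: float  # multiplies the network's source rate


@dataclass(frozen=True)
class ProjectionSpec:
    """A directed projection between two populations."""

    source: str
    target: str
    probability: float
    strength: float           # nS
    receptor: str             # "AMPA" or "GABA"
    delay: float = 0.0        # ms

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        if self.receptor not in ("AMPA", "GABA"):
            raise ValueError(f"unknown receptor {self.receptor!r}")
        expected = "AMPA" if self.source.startswith("E") else "GABA"
        if self.receptor != expected:
            raise ValueError(
                f"projection {self.source}->{self.target}: source type requires "
                f"{expected} receptor, got {self.receptor}")


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete description of one two-network experiment."""

    scenario: int
    populations: tuple[PopulationSpec, ...]
    projections: tuple[ProjectionSpec, ...]
    synapse: SynapseParams
    noise: NoiseParams
    coupling: CouplingStrengths
    duration: float = 5000.0   # ms
    dt: float = 0.05           # ms
    seed: int = 0

    def population(self, pid: str) -> PopulationSpec:
        for p in self.populations:
            if p.pid == pid:
                return p
        raise KeyError(pid)

    def __post_init__(self) -> None:
        pids = {p.pid for p in self.populations}
        for proj in self.projections:
            if proj.source not in pids or proj.target not in pids:
                raise ValueError(f"projection references unknown population "
                                 f"{proj.source}->{proj.target}")
        # Structural contracts of the scenarios: ING networks have no E
        # cells; EI networks communicate across networks only through
        # excitation.
        by_pid = {p.pid: p for p in self.populations}
        for proj in self.projections:
            cross = by_pid[proj.source].network != by_pid[proj.target].network
            if self.scenario == 1 and proj.receptor == "AMPA":
                raise ValueError("scenario 1 has no excitatory projections")
            if self.scenario in (2, 3) and cross and proj.receptor == "GABA":
                raise ValueError(
                    "scenarios 2/3 allow no inhibitory projections across networks")


# Override keys accepted by build_scenario, beyond coupling strengths and
# connection probabilities.
_SCALAR_OVERRIDES = {
    "mu_v", "sigma2", "p_ratio", "N_p", "g_P", "inh_noise_fraction",
    "duration", "dt", "seed", "delta_net", "tau_w", "V_peak",
    "N_E", "N_I",
}


def build_scenario(scenario: int, **overrides) -> ScenarioSpec:
    """Assemble a :class:`ScenarioSpec` for scenario 1, 2 or 3.

    Keyword overrides accept the flat parameter names: noise settings
    (``sigma2``, ``p_ratio``, ``mu_v``, ``N_p``, ``inh_noise_fraction``),
    coupling strengths (``J_etoe`` ... ``J_ppii``), connection probabilities
    (``p_etoe`` ... ``p_ppei``, ignored in the all-to-all scenarios),
    ``delta_net``, population sizes (``N_E``, ``N_I``), run settings
    (``duration``, ``dt``, ``seed``) and neuron-model extras (``tau_w``,
    ``V_peak``).  Unknown keys are rejected.
    """
    if scenario not in (1, 2, 3):
        raise ValueError("scenario must be 1, 2 or 3")

    coupling_keys = {f.name for f in CouplingStrengths.__dataclass_fields__.values()}
    allowed = _SCALAR_OVERRIDES | coupling_keys | set(DEFAULT_PROBABILITIES)
    unknown = set(overrides) - allowed
    if unknown:
        raise ValueError(f"unknown override keys: {sorted(unknown)}")

    noise_kwargs = {k: overrides[k] for k in
                    ("mu_v", "sigma2", "p_ratio", "N_p", "g_P",
                     "inh_noise_fraction") if k in overrides}
    noise = NoiseParams(**noise_kwargs)
    coupling = replace(CouplingStrengths(),
                       **{k: overrides[k] for k in coupling_keys if k in overrides})
    probs = dict(DEFAULT_PROBABILITIES)
    probs.update({k: overrides[k] for k in DEFAULT_PROBABILITIES if k in overrides})
    delay = float(overrides.get("delta_net", 0.0))
    duration = float(overrides.get("duration", 5000.0))
    dt = float(overrides.get("dt", 0.05))
    seed = int(overrides.get("seed", 0))

    adex_extra = {k: overrides[k] for k in ("tau_w", "V_peak") if k in overrides}
    exc = replace(EXCITATORY_ADEX, **adex_extra)
    inh = replace(INHIBITORY_ADEX, **adex_extra)

    if scenario == 1:
        n_i = int(overrides.get("N_I", 1000))
        pops = (
            PopulationSpec("I1", n_i, inh, 1, "I", 1.0),
            PopulationSpec("I2", n_i, inh, 2, "I", 1.0),
        )
        projs = (
            ProjectionSpec("I1", "I1", 1.0, coupling.J_itoi, "GABA"),
            ProjectionSpec("I2", "I2", 1.0, coupling.J_itoi, "GABA"),
            ProjectionSpec("I1", "I2", 1.0, coupling.J_ppii, "GABA", delay),
            ProjectionSpec("I2", "I1", 1.0, coupling.J_ppii, "GABA", delay),
        )
    else:
        n_e = int(overrides.get("N_E", 1000))
        n_i = int(overrides.get("N_I", 250))
        frac = noise.inh_noise_fraction
        pops = (
            PopulationSpec("E1", n_e, exc, 1, "E", 1.0),
            PopulationSpec("I1", n_i, inh, 1, "I", frac),
            PopulationSpec("E2", n_e, exc, 2, "E", 1.0),
            PopulationSpec("I2", n_i, inh, 2, "I", frac),
        )
        if scenario == 2:
            probs = {k: 1.0 for k in probs}
        projs = []
        for net in (1, 2):
            e, i = f"E{net}", f"I{net}"
            projs += [
                ProjectionSpec(e, e, probs["p_etoe"], coupling.J_etoe, "AMPA"),
                ProjectionSpec(e, i, probs["p_etoi"], coupling.J_etoi, "AMPA"),
                ProjectionSpec(i, e, probs["p_itoe"], coupling.J_itoe, "GABA"),
                ProjectionSpec(i, i, probs["p_itoi"], coupling.J_itoi, "GABA"),
            ]
        for src, tgt in ((1, 2), (2, 1)):
            projs += [
                ProjectionSpec(f"E{src}", f"E{tgt}", probs["p_ppee"],
                               coupling.J_ppee, "AMPA", delay),
                ProjectionSpec(f"E{src}", f"I{tgt}", probs["p_ppei"],
                               coupling.J_ppei, "AMPA", delay),
            ]
        projs = tuple(projs)

    return ScenarioSpec(
        scenario=scenario,
        populations=pops,
        projections=tuple(projs),
        synapse=SynapseParams(),
        noise=noise,
        coupling=coupling,
        duration=duration,
        dt=dt,
        seed=seed,
    )


def build_state(scenario: int, state: int, **overrides) -> ScenarioSpec:
    """Scenario spec for one of the canonical dynamical states (1, 2 or 3)."""
    try:
        base = dict(STATE_CONFIGS[(scenario, state)])
    except KeyError:
        raise ValueError(
            f"no canonical state configuration for scenario {scenario}, "
            f"state {state}") from None
    base.update(overrides)
    return build_scenario(scenario, **base)


@dataclass
class Adjacency:
    """Realized connectivity of one projection.

    Either dense (all-to-all, optionally minus the diagonal for recurrent
    projections) or an explicit source-indexed CSR structure (``indptr``,
    ``indices``): the targets of source neuron ``s`` are
    ``indices[indptr[s]:indptr[s+1]]``.
    """

    n_source: int
    n_target: int
    recurrent: bool
    dense: bool
    indptr: np.ndarray | None = None
    indices: np.ndarray | None = None

    @property
    def pair_count(self) -> int:
        if self.dense:
            n = self.n_source * self.n_target
            return n - self.n_source if self.recurrent else n
        return int(self.indices.shape[0])

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """All (source, target) pairs as two arrays."""
        if self.dense:
            src, tgt = np.meshgrid(np.arange(self.n_source),
                                   np.arange(self.n_target), indexing="ij")
            src, tgt = src.ravel(), tgt.ravel()
            if self.recurrent:
                keep = src != tgt
                src, tgt = src[keep], tgt[keep]
            return src, tgt
        src = np.repeat(np.arange(self.n_source),
                        np.diff(self.indptr))
        return src, self.indices.copy()

    def targets_of(self, source: int) -> np.ndarray:
        if self.dense:
            t = np.arange(self.n_target)
            return t[t != source] if self.recurrent else t
        return self.indices[self.indptr[source]:self.indptr[source + 1]]

    def propagate(self, spiked: np.ndarray) -> np.ndarray | float:
        """Presynaptic spike counts arriving at each target neuron.

        ``spiked`` is a boolean array over source neurons.  For dense
        projections the count is the total number of spiking sources (minus
        the neuron's own spike for recurrent ones), returned as an array.
        """
        if self.dense:
            total = int(np.count_nonzero(spiked))
            counts = np.full(self.n_target, float(total))
            if self.recurrent and total:
                counts[:self.n_source][spiked] -= 1.0
            return counts
        idx = np.flatnonzero(spiked)
        if not idx.size:
            return np.zeros(self.n_target)
        # Vectorized concatenation of the CSR ranges of all spiking sources.
        starts = self.indptr[idx]
        lens = self.indptr[idx + 1] - starts
        total = int(lens.sum())
        if total == 0:
            return np.zeros(self.n_target)
        cum = np.cumsum(lens)
        flat = np.arange(total) + np.repeat(starts - (cum - lens), lens)
        tgt = self.indices[flat]
        return np.bincount(tgt, minlength=self.n_target).astype(float)


def sample_adjacency(
    spec: ProjectionSpec,
    sizes: dict[str, int],
    rng: np.random.Generator,
) -> Adjacency:
    """Sample a Bernoulli-random adjacency for one projection.

    Each ordered source→target pair is included independently with the
    projection's probability; recurrent projections (source == target
    population) exclude self-pairs.  p = 1 yields the complete (minus
    diagonal) set, represented densely without sampling.
    """
    n_s, n_t = sizes[spec.source], sizes[spec.target]
    recurrent = spec.source == spec.target
    if spec.probability >= 1.0:
        return Adjacency(n_s, n_t, recurrent, dense=True)
    if spec.probability <= 0.0:
        return Adjacency(n_s, n_t, recurrent, dense=False,
                         indptr=np.zeros(n_s + 1, dtype=np.int64),
                         indices=np.empty(0, dtype=np.int64))
    mask = rng.random((n_s, n_t)) < spec.probability
    if recurrent:
        np.fill_diagonal(mask, False)
    counts = mask.sum(axis=1)
    indptr = np.zeros(n_s + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    indices = np.nonzero(mask)[1].astype(np.int64)
    return Adjacency(n_s, n_t, recurrent, dense=False,
                     indptr=indptr, indices=indices)


def write_edge_list(adjacencies: dict[str, Adjacency], path) -> None:
    """Export sampled connectivity as a three-column text edge list
    (source neuron, target neuron, projection id), for reproducibility
    audits."""
    with open(path, "w") as fh:
        fh.write("# source\ttarget\tprojection\n")
        for proj_id, adj in adjacencies.items():
            src, tgt = adj.pairs()
            for s, t in zip(src, tgt):
                fh.write(f"{s}\t{t}\t{proj_id}\n")


def read_edge_list(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read an edge list written by :func:`write_edge_list`; returns per
    projection id the (source, target) index arrays."""
    out: dict[str, list[list[int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            s, t, pid = line.split()
            out.setdefault(pid, [[], []])
            out[pid][0].append(int(s))
            out[pid][1].append(int(t))
    return {pid: (np.asarray(v[0]), np.asarray(v[1])) for pid, v in out.items()}
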