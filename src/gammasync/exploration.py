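"""Parameter explorations: 1-D/2-D sweeps, locking-threshold extraction,
state classification, and heat-map output.

A sweep runs the simulator plus the full measures pipeline over a grid of
noise parameters (typically noise strength sigma^2, optionally crossed with
the Poisson rate ratio p) and collects one long-format row per grid cell and
replicate.  Frequency-locking thresholds are read off a 1-D sweep as the
smallest sigma^2 from which the dominant-frequency ratio stays at ~1 over a
run of consecutive grid points.

State taxonomy (between-network coherence R vs within-population Kuramoto K):

* state 1 — R low, K high: independent rhythms, internally synchronized;
* state 2 — R high, K high: coupling-locked networks;
* state 3 — R high, K low: noise-locked networks (within-network
  synchronization sacrificed for between-network locking).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_build import ScenarioSpec, build_scenario, build_state
from .sim_engine import SimulationConfig, run
from .sync_measures import MeasureResult, measure_run

__all__ = [
    "SweepSpec",
    "run_sweep",
    "run_state",
    "extract_lock_threshold",
    "classify_state",
    "plot_heatmap",
]

logger = logging.getLogger("gammasync")


@dataclass(frozen=True)
class SweepSpec:
    """A 1-D or 2-D grid sweep over scenario parameters.

    ``param1``/``param2`` name flat scenario-override keys (e.g. "sigma2",
    "p_ratio", "J_ppii", "J_ppei").  Replicate seeds are derived
    deterministically from ``seed`` and the cell index.
    """

    scenario: int
    param1: str
    values1: tuple[float, ...]
    param2: str | None = None
    values2: tuple[float, ...] = ()
    replicates: int = 1
    overrides: dict = field(default_factory=dict)
    seed: int = 0
    duration: float = 3000.0   # ms
    dt: float = 0.5            # ms
    transient_discard: float = 500.0  # ms

    def __post_init__(self) -> None:
        vals = np.asarray(self.values1, dtype=float)
        if vals.size == 0 or not np.isfinite(vals).all():
            raise ValueError("values1 must be finite and non-empty")
        if self.param2 is not None:
            vals2 = np.asarray(self.values2, dtype=float)
            if vals2.size == 0 or not np.isfinite(vals2).all():
                raise ValueError("values2 must be finite and non-empty")


def _cell_seed(base: int, cell: int, rep: int) -> int:
    ss = np.random.SeedSequence([int(base), int(cell), int(rep)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _measure_row(m: MeasureResult) -> dict:
    row = {"R": m.R, "f1": m.f1, "f2": m.f2, "r": m.r, "K_mean": m.K_mean}
    for pid, k in m.K.items():
        row[f"K_{pid}"] = k
    for pid, st in m.isi.items():
        row[f"isi_mean_{pid}"] = st.mean
        row[f"isi_var_{pid}"] = st.var
    return row


def run_sweep(spec: SweepSpec, n_jobs: int = 1,
              progress: bool = False) -> pd.DataFrame:
    """Execute the sweep and return the long-format result table.

    One row per (cell, replicate) with all measures, the swept parameter
    values, the derived seed, and a status column; a failed cell is recorded
    as a failed row and the sweep continues.  Results are merged in cell
    order regardless of execution order, so the table is deterministic.
    """
    cells = []
    if spec.param2 is None:
        for i, v1 in enumerate(spec.values1):
            cells.append(((i,), {spec.param1: float(v1)}))
    else:
        for i, v1 in enumerate(spec.values1):
            for j, v2 in enumerate(spec.values2):
                cells.append(((i, j), {spec.param1: float(v1),
                                       spec.param2: float(v2)}))
    n_runs = len(cells) * spec.replicates
    logger.info("sweep: %d cells x %d replicates = %d runs of %.1f ms",
                len(cells), spec.replicates, n_runs, spec.duration)

    tasks = []
    for cell_idx, (_, params) in enumerate(cells):
        for rep in range(spec.replicates):
            tasks.append((cell_idx, rep, params))

    def _one(cell_idx: int, rep: int, params: dict) -> dict:
        seed = _cell_seed(spec.seed, cell_idx, rep)
        row = {"scenario": spec.scenario, "cell": cell_idx,
               "replicate": rep, "seed": seed, **params}
        try:
            overrides = {**spec.overrides, **params}
            sc = build_scenario(spec.scenario, **overrides)
            cfg = SimulationConfig(dt=spec.dt, duration=spec.duration,
                                   transient_discard=spec.transient_discard,
                                   seed=seed)
            m = measure_run(run(sc, cfg))
            row.update(_measure_row(m))
            row["status"] = "ok"
        except Exception as exc:  # failed cell: record and continue
            logger.warning("cell %d rep %d failed: %s", cell_idx, rep, exc)
            row["status"] = f"failed: {exc}"
        return row

    if n_jobs > 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_one)(c, r, p) for c, r, p in tasks)
    else:
        iterator = tasks
        if progress:
            try:
                from tqdm import tqdm
                iterator = tqdm(tasks, desc="sweep")
            except ImportError:
                pass
        rows = [_one(c, r, p) for c, r, p in iterator]
    df = pd.DataFrame(rows).sort_values(["cell", "replicate"],
                                        ignore_index=True)
    return df


def run_state(scenario: int, state: int, seed: int = 0,
              duration: float = 5000.0, dt: float = 0.05,
              **overrides) -> tuple[ScenarioSpec, MeasureResult]:
    """Build, simulate and measure one canonical state configuration."""
    sc = build_state(scenario, state, **overrides)
    cfg = SimulationConfig(dt=dt, duration=duration, seed=seed)
    return sc, measure_run(run(sc, cfg))


def extract_lock_threshold(result: pd.DataFrame, param: str = "sigma2",
                           r_lock: float = 0.99,
                           k_consecutive: int = 3) -> float | None:
    """Smallest swept value from which the frequency ratio stays locked.

    The locking criterion is r >= ``r_lock`` at the candidate grid point and
    at the ``k_consecutive`` subsequent points (or all remaining points if
    fewer are left).  Replicates are reduced by the median.  Returns None
    ("no threshold") if the sweep never locks.
    """
    ok = result[result["status"] == "ok"] if "status" in result else result
    med = ok.groupby(param)["r"].median().sort_index()
    vals = med.index.to_numpy()
    rs = med.to_numpy()
    n = rs.shape[0]
    for i in range(n):
        j = min(i + k_consecutive + 1, n)
        if np.all(rs[i:j] >= r_lock):
            return float(vals[i])
    return None


def classify_state(measures: MeasureResult, R_cut: float = 0.8,
                   K_cut: float = 0.6) -> str:
    """Label a run as state1 / state2 / state3 / other.

    Uses between-network R against ``R_cut`` and the mean within-population
    Kuramoto K against ``K_cut``.  state1: R low, K high; state2: both high;
    state3: R high, K low; anything else "other".  The cutoffs are reported
    responsibilities of the caller; the defaults separate the canonical
    parameter triples.
    """
    high_R = measures.R >= R_cut
    high_K = measures.K_mean >= K_cut
    if not high_R and high_K:
        return "state1"
    if high_R and high_K:
        return "state2"
    if high_R and not high_K:
        return "state3"
    return "other"


def plot_heatmap(df: pd.DataFrame, value: str, x: str = "sigma2",
                 y: str = "p_ratio", path=None, vmin: float = 0.0,
                 vmax: float = 1.0):
    """Heat map of one measure over a 2-D sweep (color scale fixed to [0,1]
    for R/K/r comparability across figures)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = df[df["status"] == "ok"] if "status" in df else df
    pivot = ok.pivot_table(index=y, columns=x, values=value,
                           aggfunc="median")
    fig, ax = plt.subplots(figsize=(6, 4))
    mesh = ax.pcolormesh(pivot.columns.to_numpy(), pivot.index.to_numpy(),
                         pivot.to_numpy(), vmin=vmin, vmax=vmax,
                         shading="nearest", cmap="viridis")
    fig.colorbar(mesh, ax=ax, label=value)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
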