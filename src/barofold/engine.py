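"""Metropolis Monte Carlo sampling and replica exchange.

The sampler works on a bead chain with rigid virtual bonds.  Moves are
either *local* (a single bead rotates while both adjacent bonds are
preserved: crankshaft for interior beads, free rotation about the
single neighbour for terminal beads) or *collective* (a bead receives
a local move and the rest of the chain, from the next bead to the end,
is rigidly shifted by the same displacement, preserving all inter-bead
vectors beyond the pivot).  One Monte Carlo cycle is N trials.

For thermodynamics, replicas at a ladder of reduced temperatures
exchange conformations with the standard parallel-tempering acceptance
rule, which leaves every per-temperature Boltzmann marginal invariant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _mc_core as core
from .contacts import ContactMap
from .model import OVERLAP, Conformation, ModelParams, total_energy

logger = logging.getLogger(__name__)

__all__ = [
    "MoveProposal",
    "EnergyTrace",
    "ReplicaSet",
    "PTConfig",
    "PTResult",
    "local_move",
    "collective_move",
    "metropolis_accept",
    "run_mc",
    "replica_exchange_step",
    "run_parallel_tempering",
    "geometric_ladder",
]


@dataclass
class MoveProposal:
    kind: str                      # "local" | "collective"
    pivot_index: int
    new_coords: np.ndarray         # full (N, 3) proposed coordinates
    delta_energy: float | None = None


@dataclass
class EnergyTrace:
    """Thinned samples from one temperature: (cycle, E*, Q, RMSD)."""

    temperature: float
    cycles: np.ndarray
    energies: np.ndarray
    q: np.ndarray
    rmsd: np.ndarray
    thin: int = 1

    def __len__(self) -> int:
        return len(self.energies)


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**63 - 1))


def local_move(
    c: Conformation, i: int, max_angle: float, rng: np.random.Generator
) -> MoveProposal:
    """Propose a single-bead rotation that preserves adjacent bond lengths."""
    n = c.n_beads
    if not (0 <= i < n):
        raise ValueError(f"bead index {i} out of range")
    state = core.seed_state(_derive_seed(rng))
    x, y, z = core.propose_local(c.coords, i, max_angle, state)
    new = c.coords.copy()
    new[i] = (x, y, z)
    return MoveProposal(kind="local", pivot_index=i, new_coords=new)


def collective_move(
    c: Conformation, k: int, rng: np.random.Generator, max_angle: float = math.pi / 6
) -> MoveProposal:
    """Local move of bead k plus a rigid shift of beads k+1..N-1.

    All inter-bead vectors beyond k are preserved exactly, so the tail
    keeps its internal geometry and only head-block interactions change.
    """
    n = c.n_beads
    if not (0 <= k < n - 1):
        raise ValueError(f"collective pivot {k} out of range (need 0 <= k < N-1)")
    state = core.seed_state(_derive_seed(rng))
    x, y, z = core.propose_local(c.coords, k, max_angle, state)
    shift = np.array([x, y, z]) - c.coords[k]
    new = c.coords.copy()
    new[k] = (x, y, z)
    new[k + 1:] += shift
    return MoveProposal(kind="collective", pivot_index=k, new_coords=new)


def metropolis_accept(delta_e: float, t: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-dE/T*))."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    if delta_e == OVERLAP or math.isnan(delta_e):
        return False
    if delta_e <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_e / t))


def run_mc(
    c0: Conformation,
    cmap: ContactMap,
    params: ModelParams,
    t: float,
    n_cycles: int,
    max_angle: float = math.pi / 6,
    p_collective: float = 0.1,
    thin: int = 10,
    seed: int = 0,
    native_ca: np.ndarray | None = None,
    mirror_symmetric_rmsd: bool = False,
    collect_frames: bool = False,
) -> tuple[EnergyTrace, Conformation] | tuple[EnergyTrace, Conformation, np.ndarray]:
    """Sample ``n_cycles`` MC cycles at reduced temperature ``t``.

    Records a thinned (E*, Q, RMSD) trace; RMSD is measured against
    ``native_ca`` (default: the starting coordinates).  With
    ``mirror_symmetric_rmsd`` the recorded RMSD is the minimum over the
    reference and its mirror image, which a distance-only potential
    cannot distinguish.  Returns the trace and the final conformation
    for chaining; with ``collect_frames`` also the (n_rec, N, 3) array
    of coordinate snapshots at the thinning points (RMSF input).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if t <= 0:
        raise ValueError("temperature must be positive")
    dnat = cmap.dnat_matrix()
    a, sigma, eps = params.well_halfwidth_a, params.hardsphere_diameter, params.epsilon
    ref = np.array(native_ca if native_ca is not None else c0.coords, dtype=float)
    ref_m = ref * np.array([1.0, 1.0, -1.0])
    coords = c0.coords.copy()
    e_cur = core.total_energy_arr(coords, dnat, a, sigma, eps)
    if e_cur == OVERLAP:
        raise ValueError("starting conformation violates the excluded volume")
    state = core.seed_state(seed)
    n_rec = n_cycles // thin
    cyc = np.empty(n_rec, dtype=np.int64)
    es = np.empty(n_rec)
    qs = np.empty(n_rec)
    rs = np.empty(n_rec)
    e_pdb = cmap.e_pdb * eps
    frames = np.empty((n_rec, len(coords), 3)) if collect_frames else None
    for k in range(n_rec):
        e_cur = core.run_cycles(coords, e_cur, dnat, a, sigma, eps, t,
                                max_angle, p_collective, thin, state)
        # re-sum to keep float drift out of long traces
        e_cur = core.total_energy_arr(coords, dnat, a, sigma, eps)
        cyc[k] = (k + 1) * thin
        es[k] = e_cur
        qs[k] = e_cur / e_pdb if e_pdb < 0 else np.nan
        rs[k] = core.rmsd_to_ref(coords, ref)
        if mirror_symmetric_rmsd:
            rs[k] = min(rs[k], core.rmsd_to_ref(coords, ref_m))
        if collect_frames:
            frames[k] = coords
    trace = EnergyTrace(temperature=t, cycles=cyc, energies=es, q=qs, rmsd=rs, thin=thin)
    final = Conformation(coords, e_cur)
    if collect_frames:
        return trace, final, frames
    return trace, final


@dataclass
class ReplicaSet:
    """Replicas at an ascending temperature ladder plus swap statistics."""

    temperatures: np.ndarray
    conformations: list[Conformation]
    energies: np.ndarray
    rng: np.random.Generator
    replica_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    swap_attempts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    swap_accepts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    parity: int = 0

    def __post_init__(self):
        m = len(self.temperatures)
        if m < 2:
            raise ValueError("need at least 2 replicas")
        if np.any(np.diff(self.temperatures) < 0):
            raise ValueError("temperature ladder must be ascending")
        if len(self.conformations) != m:
            raise ValueError("one conformation per temperature required")
        if len(self.replica_ids) != m:
            self.replica_ids = np.arange(m, dtype=np.int64)
        if len(self.swap_attempts) != m - 1:
            self.swap_attempts = np.zeros(m - 1, dtype=np.int64)
            self.swap_accepts = np.zeros(m - 1, dtype=np.int64)


def replica_exchange_step(r: ReplicaSet) -> ReplicaSet:
    """Attempt nearest-neighbour swaps (alternating even/odd pairs).

    Acceptance: min(1, exp[(1/T_i - 1/T_j)(E_i - E_j)]).
    """
    m = len(r.temperatures)
    start = r.parity % 2
    for i in range(start, m - 1, 2):
        j = i + 1
        r.swap_attempts[i] += 1
        arg = (1.0 / r.temperatures[i] - 1.0 / r.temperatures[j]) * (
            r.energies[i] - r.energies[j]
        )
        if arg >= 0 or r.rng.random() < math.exp(arg):
            r.conformations[i], r.conformations[j] = r.conformations[j], r.conformations[i]
            r.energies[i], r.energies[j] = r.energies[j], r.energies[i]
            r.replica_ids[i], r.replica_ids[j] = r.replica_ids[j], r.replica_ids[i]
            r.swap_accepts[i] += 1
    r.parity += 1
    return r


def geometric_ladder(t_min: float, t_max: float, n: int) -> np.ndarray:
    """Geometrically spaced reduced-temperature ladder."""
    if not (0 < t_min < t_max) or n < 2:
        raise ValueError("need 0 < t_min < t_max and n >= 2")
    return np.geomspace(t_min, t_max, n)


@dataclass
class PTConfig:
    """Parallel-tempering run configuration (scaled-down defaults)."""

    temperatures: np.ndarray
    n_cycles: int = 100_000
    n_thermalization: int = 20_000
    thin: int = 20
    swap_every: int = 10
    max_angle: float = math.pi / 6
    p_collective: float = 0.1
    n_runs: int = 1
    seed: int = 0
    save_pool_top: int = 2         # rungs (from the top) whose snapshots feed kinetics
    pool_every: int = 100          # cycles between pool snapshots
    mirror_symmetric_rmsd: bool = False

    def validate(self) -> None:
        if len(self.temperatures) < 2:
            raise ValueError("ladder needs >= 2 temperatures")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("ladder must be strictly increasing")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1 (thermalization may not consume the whole run)")
        if self.n_thermalization < 0:
            raise ValueError("n_thermalization must be >= 0")
        if self.thin % self.swap_every != 0 or self.pool_every % self.swap_every != 0:
            raise ValueError("thin and pool_every must be multiples of swap_every")


@dataclass
class PTResult:
    """Traces per run x temperature, swap statistics and an unfolded pool."""

    traces: list[list[EnergyTrace]]
    swap_acceptance: np.ndarray            # (n_runs, n_temps - 1)
    ladder_span_counts: list[int]          # replicas that visited both ends, per run
    unfolded_pool: list[np.ndarray]        # coordinate snapshots from the top rungs
    config: PTConfig


def run_parallel_tempering(
    config: PTConfig,
    cmap: ContactMap,
    params: ModelParams,
    native: Conformation,
) -> PTResult:
    """Replica-exchange MC over the ladder, repeated over independent runs.

    Every replica starts from the native conformation; thermalization
    samples are discarded.  Returns per-run, per-temperature traces of
    (E*, Q, RMSD) plus snapshots from the hottest rungs that serve as
    the unfolded starting pool for kinetic simulations.
    """
    config.validate()
    temps = np.asarray(config.temperatures, dtype=float)
    m = len(temps)
    dnat = cmap.dnat_matrix()
    a, sigma, eps = params.well_halfwidth_a, params.hardsphere_diameter, params.epsilon
    e_pdb = cmap.e_pdb * eps
    native_ca = np.array(native.coords, dtype=float)
    native_m = native_ca * np.array([1.0, 1.0, -1.0])
    total_cycles = config.n_thermalization + config.n_cycles
    if config.n_cycles < config.thin:
        logger.warning("production shorter than the thinning interval; traces will be empty")

    all_traces: list[list[EnergyTrace]] = []
    swap_acc = np.zeros((config.n_runs, m - 1))
    span_counts: list[int] = []
    pool: list[np.ndarray] = []
    master = np.random.SeedSequence(config.seed)
    run_seeds = master.spawn(config.n_runs)

    for run in range(config.n_runs):
        ss = run_seeds[run]
        swap_rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
        rep_seeds = [int(s.generate_state(1, np.uint64)[0] >> 1) or 1 for s in ss.spawn(m)]
        states = [core.seed_state(sd) for sd in rep_seeds]
        coords = [native_ca.copy() for _ in range(m)]
        energies = np.array([core.total_energy_arr(c, dnat, a, sigma, eps) for c in coords])
        replica_ids = np.arange(m)
        visited_lo = np.zeros(m, dtype=bool)
        visited_hi = np.zeros(m, dtype=bool)
        parity = 0

        recs: list[list[tuple[int, float, float, float]]] = [[] for _ in range(m)]
        n_seg = total_cycles // config.swap_every
        for seg in range(n_seg):
            cycle = (seg + 1) * config.swap_every
            for r_i in range(m):
                energies[r_i] = core.run_cycles(
                    coords[r_i], energies[r_i], dnat, a, sigma, eps, temps[r_i],
                    config.max_angle, config.p_collective, config.swap_every, states[r_i],
                )
            # nearest-neighbour swaps, alternating parity
            for i in range(parity % 2, m - 1, 2):
                arg = (1.0 / temps[i] - 1.0 / temps[i + 1]) * (energies[i] - energies[i + 1])
                if arg >= 0 or swap_rng.random() < math.exp(arg):
                    coords[i], coords[i + 1] = coords[i + 1], coords[i]
                    energies[i], energies[i + 1] = energies[i + 1], energies[i]
                    replica_ids[i], replica_ids[i + 1] = replica_ids[i + 1], replica_ids[i]
                    swap_acc[run, i] += 1
            parity += 1
            visited_lo[replica_ids[0]] = True
            visited_hi[replica_ids[-1]] = True
            if cycle <= config.n_thermalization:
                continue
            prod_cycle = cycle - config.n_thermalization
            if prod_cycle % config.thin < config.swap_every:
                for r_i in range(m):
                    e = core.total_energy_arr(coords[r_i], dnat, a, sigma, eps)
                    energies[r_i] = e
                    q = e / e_pdb if e_pdb < 0 else np.nan
                    rms = core.rmsd_to_ref(coords[r_i], native_ca)
                    if config.mirror_symmetric_rmsd:
                        rms = min(rms, core.rmsd_to_ref(coords[r_i], native_m))
                    recs[r_i].append((prod_cycle, e, q, rms))
            if prod_cycle % config.pool_every < config.swap_every:
                for r_i in range(max(0, m - config.save_pool_top), m):
                    pool.append(coords[r_i].copy())

        n_half_sweeps = max(1, n_seg)
        swap_acc[run] /= (n_half_sweeps / 2.0)  # each pair attempted every other segment
        span_counts.append(int((visited_lo & visited_hi).sum()))
        run_traces = []
        for r_i in range(m):
            arr = np.array(recs[r_i]) if recs[r_i] else np.zeros((0, 4))
            run_traces.append(
                EnergyTrace(
                    temperature=temps[r_i],
                    cycles=arr[:, 0].astype(np.int64) if len(arr) else np.zeros(0, dtype=np.int64),
                    energies=arr[:, 1] if len(arr) else np.zeros(0),
                    q=arr[:, 2] if len(arr) else np.zeros(0),
                    rmsd=arr[:, 3] if len(arr) else np.zeros(0),
                    thin=config.thin,
                )
            )
        all_traces.append(run_traces)

    return PTResult(
        traces=all_traces,
        swap_acceptance=swap_acc,
        ladder_span_counts=span_counts,
        unfolded_pool=pool,
        config=config,
    )
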