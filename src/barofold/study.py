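"""Canned study protocols: the full pipeline at fixture scale.

This module wires the package end to end the way the full-scale
protein studies are run — contact maps per pressure, replica-exchange
thermodynamics, WHAM analysis, and first-passage kinetics — at sizes a
laptop handles in minutes.  The same functions drive the test suite,
the acceptance script and (with larger settings) full reproductions.

Conventions fixed here (see docs/methods.md for rationale):

* The temperature ladder concentrates rungs around the fixture's
  folding transition so replicas flow freely through it; flow was
  verified by swap-acceptance and ladder-span diagnostics.
* T_m comes from the Cv peak of the WHAM density of states pooled over
  independent runs (the run-averaging the full-scale protocol uses).
* Room temperature T_r = 0.9 T_m and the RMSD folding threshold (the
  90%-framing quantile at the rung nearest T_r) are both fixed from
  the room-pressure system and reused at every pressure, so kinetic
  comparisons across pressures share one criterion.
* RMSD is recorded enantiomer-aware: a distance-only potential cannot
  distinguish a fold from its mirror image, so the folded basin is the
  enantiomer pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactMap, build_contact_map
from .engine import PTConfig, PTResult, run_parallel_tempering
from .fixtures import ToySpec, make_pressure_series
from .kinetics import (
    FirstPassageRecord,
    folding_threshold_from_traces,
    run_kinetics_ensemble,
)
from .model import ModelParams, native_conformation
from .structure import Structure
from .thermo import cv_curve, cv_from_wham, melting_temperature, pool_runs, wham

__all__ = [
    "FIXTURE_LADDER",
    "ThermoStudy",
    "run_thermo_study",
    "PressurePoint",
    "run_pressure_study",
    "default_fixture_spec",
]

#: Reduced-temperature ladder for the 22-bead compact fixture: rungs are
#: concentrated around its folding transition (T_m ~ 0.36) so that
#: nearest-neighbour swap acceptance stays well away from zero.
FIXTURE_LADDER = np.array([0.26, 0.30, 0.33, 0.355, 0.38, 0.41, 0.46, 0.55])


def default_fixture_spec(seed: int = 3) -> ToySpec:
    """The work-horse fixture: 22-bead compact solenoid."""
    return ToySpec(
        n_residues=22, topology="compact", perturbation=0.1,
        contact_bias=1.0, seed=seed,
    )


@dataclass
class ThermoStudy:
    """Thermodynamic characterisation of one structure at one pressure."""

    contact_map: ContactMap
    params: ModelParams
    pt: PTResult
    pooled_traces: list
    tm: float
    cv_ladder: object          # CvCurve on the sampled ladder (run-averaged)
    cv_fine: object            # CvCurve on the WHAM-reweighted fine grid
    wham_result: object


def run_thermo_study(
    s: Structure,
    seed: int,
    n_runs: int = 8,
    n_cycles: int = 100_000,
    n_thermalization: int = 30_000,
    temperatures: np.ndarray | None = None,
    fine_grid: np.ndarray | None = None,
) -> ThermoStudy:
    """Replica-exchange thermodynamics of one structure.

    Builds the contact map and model, runs ``n_runs`` independent
    parallel-tempering repetitions, pools them into a WHAM solution and
    locates T_m on a reweighted fine temperature grid.
    """
    temps = FIXTURE_LADDER if temperatures is None else np.asarray(temperatures)
    cm = build_contact_map(s)
    params = ModelParams.from_structure(s)
    nat = native_conformation(s, cm, params)
    cfg = PTConfig(
        temperatures=temps,
        n_cycles=n_cycles,
        n_thermalization=n_thermalization,
        thin=20,
        swap_every=5,
        n_runs=n_runs,
        seed=seed,
        mirror_symmetric_rmsd=True,
    )
    pt = run_parallel_tempering(cfg, cm, params, nat)
    pooled = pool_runs(pt.traces)
    w = wham(pooled)
    if fine_grid is None:
        # stay just inside the sampled range so the peak is interior
        fine_grid = np.linspace(temps[1], 0.98 * temps[-1], 141)
    fine = cv_from_wham(w, fine_grid)
    tm = melting_temperature(fine)
    return ThermoStudy(
        contact_map=cm,
        params=params,
        pt=pt,
        pooled_traces=pooled,
        tm=tm,
        cv_ladder=cv_curve(pt.traces),
        cv_fine=fine,
        wham_result=w,
    )


@dataclass
class PressurePoint:
    pressure: float
    n_contacts: int
    tm: float
    threshold: float
    t_r: float
    records: list[FirstPassageRecord] = field(default_factory=list)
    q_samples: np.ndarray = field(default_factory=lambda: np.zeros(0))
    rmsd_samples: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def median_fpt(self) -> float:
        t = np.array([np.inf if r.censored else r.cycles_to_fold for r in self.records])
        return float(np.median(t)) if len(t) else float("nan")

    @property
    def folded_fraction(self) -> float:
        return 1.0 - np.mean([r.censored for r in self.records]) if self.records else 0.0


def run_pressure_study(
    seed: int,
    n_pressures: int = 3,
    n_runs: int = 4,
    n_trajectories: int = 150,
    cap: int = 200_000,
    fixture_seed: int = 3,
    with_kinetics: bool = True,
) -> list[PressurePoint]:
    """Thermo + kinetics across an add-contacts pseudo-pressure series.

    Emulates the lysozyme phenomenology: pressure only adds native
    contacts.  The comparison across pressures is controlled: T_r and
    the folding threshold are fixed from the room-pressure entry, and
    every pressure starts its trajectories from the same unfolded pool
    (drawn from the room-pressure high-temperature replicas) with the
    same per-trajectory seeds, so pressures differ only through their
    contact maps.
    """
    series = make_pressure_series(default_fixture_spec(fixture_seed), n_pressures,
                                  mode="add-contacts")
    ss = np.random.SeedSequence(seed)
    pt_seed, kin_seed = [int(x.generate_state(1, np.uint64)[0] >> 33) for x in ss.spawn(2)]
    points: list[PressurePoint] = []
    t_r = float("nan")
    threshold = float("nan")
    pool: list[np.ndarray] = []
    for s in series.entries:
        st = run_thermo_study(s, seed=pt_seed, n_runs=n_runs)
        if np.isnan(t_r):
            t_r = 0.9 * st.tm
            threshold = folding_threshold_from_traces(st.pooled_traces, t_r)
            pool = st.pt.unfolded_pool
        point = PressurePoint(
            pressure=s.pressure_label,
            n_contacts=st.contact_map.n_contacts,
            tm=st.tm,
            threshold=threshold,
            t_r=t_r,
        )
        if with_kinetics:
            recs, qs, rs = run_kinetics_ensemble(
                pool, st.contact_map, st.params, s.ca,
                threshold, t_r, cap=cap, n_trajectories=n_trajectories,
                seed=kin_seed, mirror_symmetric=True,
            )
            point.records = recs
            point.q_samples = qs
            point.rmsd_samples = rs
        points.append(point)
    return points
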