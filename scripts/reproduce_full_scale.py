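"""Reproduction driver for the experimental multi-pressure proteins.

Runs the complete pipeline on the deposited lysozyme (HEWL) or DHFR
structure series: contact maps and difference maps, replica-exchange
thermodynamics (Cv curves, T_m per pressure, WHAM free-energy profiles
at T_m and T_r), and first-passage kinetics with survival curves.

Requires the PDB files under data/pdb/ (run scripts/fetch_pdb.py once,
network needed).  The default settings are desk-scale so the script
finishes in hours on one core; ``--full`` switches to the full
production protocol (50 temperatures, 3e6 thermalization + 1e7
recording cycles, 10 independent runs, 1e4 trajectories), which is a
multi-week single-core computation — run it on a cluster, one
(protein, pressure, run) per job.

Usage:
    python scripts/reproduce_full_scale.py --protein hewl --out scratch/hewl
    python scripts/reproduce_full_scale.py --protein dhfr --full --out scratch/dhfr
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

PROTEINS = {
    "hewl": [("4WLD", 0.001), ("4WLT", 1.9), ("4WLY", 3.8), ("4WM2", 6.0)],
    "dhfr": [("5Z6F", 0.001), ("5Z6J", 2.2), ("5Z6K", 4.0), ("5Z6M", 8.0)],
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--protein", choices=sorted(PROTEINS), required=True)
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--full", action="store_true",
                    help="full production protocol (very long; see module docstring)")
    ap.add_argument("--t-min", type=float, default=0.7)
    ap.add_argument("--t-max", type=float, default=1.6)
    args = ap.parse_args()

    from barofold.contacts import build_contact_map, difference_map
    from barofold.engine import PTConfig, geometric_ladder, run_parallel_tempering
    from barofold.kinetics import (
        fit_kinetic_model, folding_threshold_from_traces, run_kinetics_ensemble,
        survival_curve,
    )
    from barofold.model import ModelParams, native_conformation
    from barofold.structure import kabsch_rmsd, parse_structure
    from barofold.thermo import (
        cv_curve, cv_from_wham, free_energy_profile, melting_temperature,
        pool_runs, wham,
    )

    if args.full:
        n_temps, n_cycles, n_therm, n_runs, n_traj = 50, 10_000_000, 3_000_000, 10, 10_000
    else:
        n_temps, n_cycles, n_therm, n_runs, n_traj = 16, 300_000, 100_000, 2, 500

    data = Path(__file__).resolve().parent.parent / "data" / "pdb"
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    summary = []
    t_r = None
    threshold = None
    pool = None
    ref_struct = None
    ref_map = None
    for pdb_id, pressure in PROTEINS[args.protein]:
        s = parse_structure((data / f"{pdb_id}.pdb").read_text(), chain_id="A",
                            pressure_label=pressure, source_id=pdb_id)
        cm = build_contact_map(s)
        params = ModelParams.from_structure(s)
        nat = native_conformation(s, cm, params)
        if ref_struct is None:
            ref_struct, ref_map = s, cm
            rmsd_to_ref = 0.0
        else:
            rmsd_to_ref = kabsch_rmsd(s.ca, ref_struct.ca)
            d = difference_map(cm, ref_map)
            pd.DataFrame(
                [{"i": i, "j": j, "change": "gained"} for i, j in sorted(d.gained)]
                + [{"i": i, "j": j, "change": "lost"} for i, j in sorted(d.lost)]
            ).to_csv(out / f"diff_contacts_{pdb_id}.csv", index=False)

        cfg = PTConfig(
            temperatures=geometric_ladder(args.t_min, args.t_max, n_temps),
            n_cycles=n_cycles, n_thermalization=n_therm, thin=100,
            swap_every=10, n_runs=n_runs, seed=args.seed,
            mirror_symmetric_rmsd=True,
        )
        res = run_parallel_tempering(cfg, cm, params, nat)
        pooled = pool_runs(res.traces)
        w = wham(pooled)
        curve = cv_curve(res.traces)
        pd.DataFrame({"T": curve.temperatures, "Cv": curve.cv, "err": curve.errors}
                     ).to_csv(out / f"cv_{pdb_id}.csv", index=False)
        fine = cv_from_wham(w, np.linspace(cfg.temperatures[1],
                                           0.98 * cfg.temperatures[-1], 301))
        tm = melting_temperature(fine)
        if t_r is None:
            t_r = 0.9 * tm
            threshold = folding_threshold_from_traces(pooled, t_r)
            pool = res.unfolded_pool
        for label, t in (("Tm", tm), ("Tr", t_r)):
            prof = free_energy_profile(w, pooled, t, q_bins=100)
            pd.DataFrame({"Q": prof.q_centers, "F": prof.f}).to_csv(
                out / f"fq_{label}_{pdb_id}.csv", index=False)

        recs, qs, rs = run_kinetics_ensemble(
            pool, cm, params, s.ca, threshold, t_r, cap=50 * n_cycles // 100,
            n_trajectories=n_traj, seed=args.seed + 1, mirror_symmetric=True,
        )
        sc = survival_curve(recs)
        pd.DataFrame({"cycle": sc.grid, "surviving": sc.surviving}).to_csv(
            out / f"survival_{pdb_id}.csv", index=False)
        try:
            fit = fit_kinetic_model(sc)
            n_comp = fit.n_components
        except (ValueError, RuntimeError):
            n_comp = None
        np.savez(out / f"qr_{pdb_id}.npz", q=qs, rmsd=rs)

        fpt = np.array([np.inf if r.censored else r.cycles_to_fold for r in recs])
        summary.append({
            "pdb": pdb_id, "pressure_kbar": pressure,
            "n_contacts": cm.n_contacts, "rmsd_to_1bar": round(rmsd_to_ref, 3),
            "tm": round(tm, 5),
            "tm_over_tm_1bar": round(tm / summary[0]["tm"], 5) if summary else 1.0,
            "t_r": round(t_r, 5),
            "threshold_A": round(threshold, 3),
            "median_fpt": None if not np.isfinite(np.median(fpt)) else float(np.median(fpt)),
            "folded_fraction": float(np.isfinite(fpt).mean()),
            "kinetic_components": n_comp,
        })
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        print(json.dumps(summary[-1]))


if __name__ == "__main__":
    main()
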