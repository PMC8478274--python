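# barofold

Structure-based (Gō-type) folding simulations in which **pressure enters only
through the experimental native structure**. Proteins solved by X-ray or NMR at
several pressures differ by fractions of an Ångström, yet those differences
add and remove native contacts. `barofold` builds a contact map per pressure,
runs coarse-grained Monte Carlo on the resulting models, and extracts the
thermodynamic and kinetic signatures of pressure — no pressure-dependent
potential required.

It is aimed at molecular-simulation practitioners who want to ask: *are the
tiny structural changes induced by pressure enough to shift folding stability
and speed in a minimal model?*

## Model

The chain is N beads (one per residue) with rigid virtual bonds fixed at the
native Cα–Cα distances. Residue pairs (i, j) with |i − j| ≥ 4 whose heavy
atoms approach within 4.5 Å in the deposited structure are native contacts;
each contributes a truncated harmonic well centred on the native Cα distance
d̂ᵢⱼ:

    u(r) = ε [ ((r − d̂ᵢⱼ)/a)² − 1 ]   for |r − d̂ᵢⱼ| ≤ a,    0 otherwise

with ε = 1 the reduced energy unit and a = 0.6 Å the well half-width. All
non-bonded pairs also feel a hard-sphere repulsion (default diameter 4.0 Å).
The native conformation therefore has reduced energy E*₍native₎ = −(number of
contacts), and the folding coordinate of a sampled conformation is

    Q = E*₍sampled₎ / E*₍native₎  ∈ (…, 1].

Sampling is Metropolis Monte Carlo with single-bead crankshaft/terminal
rotations and collective tail-shift moves (one cycle = N trials), wrapped in
replica exchange over a reduced-temperature ladder for thermodynamics. Heat
capacity follows from energy fluctuations, C*ᵥ = (⟨E*²⟩ − ⟨E*⟩²)/T*², the
melting temperature T*ₘ is the Cᵥ peak (refined on a WHAM-reweighted fine
grid), and free-energy profiles F*(Q) = −T* ln p(Q) come from the WHAM density
of states. Folding kinetics are first-passage simulations at the room
temperature T*ᵣ = 0.9 T*ₘ: local moves only, stopping when the Cα RMSD to the
native structure drops below the threshold that frames 90 % of the equilibrium
conformations at T*ᵣ; survival curves 1 − P_N(t) are fitted with sums of
exponentials (amplitudes summing to one, signs free, so sequential
intermediate mechanisms with lag phases are representable).

One caveat is built into the package: a distance-only potential cannot
distinguish a fold from its mirror image, so the folded basin is really an
enantiomer pair. RMSD-based criteria can optionally (and by default in the
CLI) take the minimum over the reference and its mirror; see
`docs/methods.md`.

## Worked example

Generate a small pseudo-pressure series (a 22-residue compact fixture whose
contact count grows with "pressure" while the backbone moves < 0.2 Å) and push
it through the pipeline:

```bash
$ barofold fixtures make --n-residues 22 --topology compact \
      --n-pressures 3 --mode add-contacts --seed 3 --out structures
wrote 3 structures to structures

$ barofold structure-info structures/toy-compact-22-s3.pdb
{"source": "toy-compact-22-s3", "N": 22, "Rg": 6.303, "bfactors": [11.173, ...]}

$ barofold contacts structures/toy-compact-22-s3.pdb --out contacts_room.csv
{"source": "toy-compact-22-s3", "N": 22, "count": 29, "cutoff": 4.5, "min_separation": 4}

$ barofold diff-contacts structures/toy-compact-22-s3-p2.pdb structures/toy-compact-22-s3.pdb
{"gained": 4, "lost": 0, "net": 4}

$ barofold rmsd structures/toy-compact-22-s3-p2.pdb structures/toy-compact-22-s3.pdb
0.080
```

So the top "pressure" adds 4 native contacts while moving the Cα trace by
only 0.08 Å RMSD — the same phenomenology the real lysozyme series shows.
Now thermodynamics (about half a minute) and kinetics, driven by an INI
config:

```ini
# thermo.ini
[model]
pdb = structures/toy-compact-22-s3.pdb

[ladder]
t_min = 0.26
t_max = 0.55
n_temps = 8

[sampling]
n_cycles = 100000
n_thermalization = 30000
thin = 20
swap_every = 10
n_runs = 4

[kinetics]
cap = 200000
n_trajectories = 200

[seeds]
seed = 11
```

```bash
$ barofold thermo-run thermo.ini --out run_room
wrote 32 traces to run_room
$ barofold thermo-analyze run_room --out analysis_room
{"T_m": 0.35999, "T_r": 0.32399}

$ barofold kinetics-run thermo.ini --pool run_room/unfolded_pool.npy --t-r 0.324 --out kin_room
{"threshold": 3.758, "censored": 0}
$ barofold kinetics-analyze kin_room/first_passage.csv
{"n_components": 3, "rates": [0.000445..., 6.56e-05, 6.51e-05],
 "amplitudes": [-0.430, 53.6, -52.2], "plateau": 0.0,
 "single_exponential_chi2": 1379.9, "chi2": 7.1}
```

Reading the numbers: the fixture melts at T*ₘ ≈ 0.360; at T*ᵣ = 0.324 the
folding criterion is 3.76 Å and all 200 trajectories fold. A single
exponential is a poor description of the survival curve (χ² ≈ 1380 vs 7 for
the selected model): the negative fast amplitude is a lag (collapse) phase,
and the near-degenerate slow pair is the equal-rates limit of two sequential
steps — the model chain folds through intermediates, not in one barrier hop.
Native-state fluctuations respond to the added contacts:

```bash
$ barofold fluct structures/toy-compact-22-s3.pdb -t 0.324 --seed 1
{"mean_rmsf": 2.2718, "max_rmsf": 5.0719}
$ barofold fluct structures/toy-compact-22-s3-p2.pdb -t 0.324 --seed 1
{"mean_rmsf": 1.6556, "max_rmsf": 3.0794}
```

— the high-pressure model is stiffer, mirroring the experimental B-factor
ratios falling below one.

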