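# Methods

## Model

The protein is a linear chain of N beads at the Cα positions. Consecutive
beads are connected by rigid virtual bonds fixed at the native Cα–Cα
distances (typically ≈ 3.8 Å); bond lengths are conserved exactly by every
Monte Carlo move, so the model has no bond-stretching term.

**Native contacts.** A residue pair (i, j) is a native (tertiary) contact if
|i − j| ≥ 4 and any two heavy atoms, one from each residue, are within 4.5 Å
(inclusive) in the deposited structure. Contact *detection* is atomic;
contact *interaction distances* d̂ᵢⱼ are the native Cα–Cα distances — a
two-scale convention: atoms decide whether residues touch, beads carry the
interaction. Pairs at |i − j| = 1, 2, 3 define the local chain geometry
(virtual bonds and angles) and carry no attractive term; local stiffness
emerges from the contacts alone.

**Potential.** Each contact contributes a truncated harmonic well,

u(r) = ε[((r − d̂ᵢⱼ)/a)² − 1] for |r − d̂ᵢⱼ| ≤ a, and 0 outside,

with ε = 1 (the reduced energy unit) and half-width a = 0.6 Å. The form is
the simplest continuous well with the required properties (harmonic, depth ε,
width a, centred on the native distance, continuous at truncation). Because
u ≥ −ε everywhere, the native conformation is the exact ground state with
E* = −(number of contacts) and the folding coordinate Q = E*/E*₍native₎ never
exceeds 1.

**Excluded volume.** Every non-bonded bead pair carries a hard-sphere
repulsion of diameter σ = 4.0 Å (configurable); any violation carries
infinite energy and is never accepted. Two qualifications:

* bonded neighbours (|i − j| = 1) are exempt — their distance is fixed anyway;
* a native-contact pair whose well reaches below σ (d̂ᵢⱼ − a < σ) is exempt
  *inside its well range*. Without this rule a structure with short native
  Cα distances would reject its own native state. The model build validates
  the native conformation against the hard sphere and reports how many
  contacts use the exemption.

**Chirality.** A distance-only potential is blind to handedness: the mirror
image of any conformation has identical energy, so the "native state" is
really an enantiomer pair, and equilibrium ensembles of small chains visit
the mirror basin with substantial probability. All RMSD-based machinery
(trace recording, folding criterion) therefore accepts an *enantiomer-aware*
mode in which the RMSD is the minimum over the reference and its mirror
image. The pure proper-rotation Kabsch RMSD remains the primitive; the
mirror-aware mode is a composition of two such calls. Study pipelines and
the CLI default to the mirror-aware criterion; the low-level operations
default to the plain one. For large natural proteins the mirror basin is
kinetically remote and the two conventions rarely differ; for minimal
fixtures the plain criterion censors roughly half of all folding
trajectories (they fold into the mirror), which is worth knowing before
interpreting a survival plateau.

## Sampling

**Moves.** A *local* move rotates one bead: interior beads crank about the
axis through their two neighbours, terminal beads rotate about a random axis
through their single neighbour; angles are uniform in [−θₘₐₓ, θₘₐₓ] with
θₘₐₓ = π/6 by default. A *collective* move gives bead k a local move and
rigidly shifts beads k+1…N−1 by the same displacement, preserving all
inter-bead vectors beyond the pivot. One Monte Carlo cycle is N Metropolis
trials; by default 10 % of trials propose collective moves (equilibrium
sampling) and kinetic runs use local moves only, which keeps the kinetic
dynamics local and interpretable as a time proxy. Acceptance is standard
Metropolis, min(1, e^(−ΔE*/T*)), with hard-sphere overlaps always rejected.

**Replica exchange.** For thermodynamics, replicas at an ascending ladder of
reduced temperatures attempt nearest-neighbour swaps every 5–10 cycles
(alternating even/odd pairs) with acceptance min(1, exp[(1/Tᵢ − 1/Tⱼ)(Eᵢ −
Eⱼ)]). Swap acceptance per rung pair and the number of replicas that visit
both ends of the ladder are recorded as mixing diagnostics; ladders should be
chosen so neither collapses near the folding transition. Every replica
starts from the native conformation and a thermalization segment is
discarded. Each run keeps one deterministic xorshift128+ stream per replica,
seeded via splitmix64 from the master seed, so traces are bit-reproducible.

**Traces.** Thinned samples record (cycle, E*, Q, RMSD-to-native). Energies
are re-summed from scratch at every record to keep floating-point drift out
of long delta-tracked runs.

## Analysis

**Heat capacity and T_m.** C*ᵥ = var(E*)/T*² per rung; run-to-run spread over
independent runs gives the error bars. The melting temperature is the
absolute maximum of C*ᵥ, located on a fine temperature grid by reweighting
the WHAM density of states (energy moments at arbitrary T*), with parabolic
refinement; a maximum at the grid edge is an error, not an answer. Ties
resolve to the lower temperature with a warning.

**WHAM.** The standard self-consistent multi-histogram equations on binned
energies (default bin width 1 ε — one contact depth; use finer bins for
systems whose whole energy range is a few ε). Iteration stops when the log
normalizers change by < 1e−7; adjacent-rung histogram overlap is diagnosed
and zero overlap raises. Free-energy profiles F*(Q) = −T* ln p(Q) use
per-sample reweighting (Q is recorded jointly with E*, so no approximation
beyond the energy binning of the normalizers); the minimum is shifted to
zero and empty bins are flagged as NaN, never interpolated. Independent runs
are pooled before WHAM: each run samples the same equilibrium, and pooling
averages out the slow folded/unfolded flipping of individual runs near the
transition.

**Kinetics.** Room temperature is T*ᵣ = 0.9 T*ₘ. In cross-pressure studies
both T*ᵣ and the folding threshold are fixed once, from the room-pressure
system, and reused at every pressure: room temperature does not move with
pressure, and a common criterion is the only way the first-passage times are
comparable. The threshold is the 0.9 quantile (lower tail) of the RMSD
distribution at the replica-exchange rung nearest T*ᵣ — the PT ensemble is
used rather than a fresh single-temperature run because exchange keeps that
rung equilibrated. Trajectories start from conformations saved from the two
hottest rungs, run local-only Metropolis at T*ᵣ, check the RMSD every cycle
and stop at the first cycle under the threshold; a cap (default 2 × 10⁵
cycles at fixture scale) censors non-folders, and censoring is always
reported. Survival curves 1 − P_N are evaluated on a log-spaced cycle grid
with censored trajectories surviving through the cap.

**Kinetic fits.** Candidate models with 1…4 exponential components are
fitted by weighted least squares (per-point binomial standard errors) with
rates constrained to the resolvable window of the grid and amplitudes
summing to 1 − plateau but individually free in sign: sequential
intermediate mechanisms produce exponential sums with negative components
(the lag phase), which non-negative mixtures cannot represent. Two starts
per component count (plain mixture and lag-type) guard against the
single-exponential local minimum; the reported model minimises AIC and the
single-exponential χ² is always reported so its inadequacy is a measured
statistic. A near-degenerate rate pair with large opposite amplitudes is the
equal-rates limit of two sequential steps (t·e^(−kt) behaviour), not a
pathology.

**Fluctuations.** RMSF profiles superpose every frame onto the native Cα
reference (Kabsch, all residues, unit weights) and take the per-residue RMS
deviation; standard errors come from block averaging over five contiguous
trajectory segments, which discounts serial correlation. Pressure responses
are per-residue ratios against the room-pressure profile; experimental
B-factor ratios (per-residue means over heavy atoms, or Cα only) are the
measured counterpart.

## Structure input conventions

PDB parsing keeps protein residues only: hydrogens, waters and hetero
compounds (ligands, ions) are dropped — for the DHFR crystal structures this
removes the folate/NADP ligands, matching the chain-only model. Alternate
locations resolve to the highest occupancy, first record on tie (the common
crystallographic convention; it can shift contact counts by ±1–2, which is
why the structural acceptance check tolerates ±2). Multi-model (NMR) files
read one model, the first by default. Chains default to the first protein
chain; multi-chain crystals should pass `--chain A` explicitly. Residues are
indexed 0…N−1 in chain order; author numbering is kept for reporting only,
and sequence gaps are not filled — |i − j| separation uses the sequential
index.

## Synthetic fixtures

The generator produces protein-like toys with ~3.8 Å virtual bonds and dummy
side-chain atoms offset ±1.2–1.4 Å from the Cα, so atomic contact detection
is exercised on coordinates distinct from the interaction centres:

* **helix** — an α-helix-like spiral (i, i+4 contacts);
* **hairpin** — two antiparallel strands 4.6 Å apart with side-chain dummies
  pointing across the gap, so contacts exist at the atomic scale while the
  Cα distances stay outside both the cutoff and the hard sphere;
* **compact** — a solenoid (8 beads per turn, 5 Å pitch) whose stacked turns
  give ≈ 1.5 contacts per residue; the work-horse for folding studies.

Pseudo-pressure series emulate the two experimental phenomenologies.
*add-contacts* (lysozyme-like) applies small targeted displacements — the
two residues of a near-cutoff pair move toward each other, neighbours
following at half amplitude — accepted only if no existing contact is lost,
so the maps are nested by construction and the backbone moves < 0.2 Å RMSD.
*mixed* (DHFR-like) compresses one half of the chain and dilates the other
so contacts both appear and disappear. The default study series gains 6
contacts per pressure step on a 29-contact reference; real pressure series
gain proportionally less (a few % of contacts), but at fixture scale the
effect must clear the statistical resolution of a few hundred trajectories,
so the generator's step is chosen for detectability, not literal realism.

What the fixtures do **not** emulate: real side-chain packing, sequence
heterogeneity, disulfide bonds, ligand cavities, and the system sizes at
which transitions sharpen. Fixture-scale transitions are broad: at
T*ᵣ = 0.9 T*ₘ a 22-bead chain still has a 20–30 % partially-unfolded
equilibrium fraction, so the 90 %-framing threshold lands on the disordered
shoulder of the RMSD distribution and fluctuates between repeats. Passing
fixture tests shows the machinery is correct and the qualitative mechanism
(more contacts → higher T*ₘ, faster folding, damped fluctuations) operates;
quantitative statements about real proteins require the full-scale runs.

## Scaled-down study conditions

The canned protocols in `barofold.study` freeze the fixture-scale
conditions: the 22-residue compact fixture (seed 3, 0.1 Å backbone jitter);
the 8-rung ladder [0.26, 0.30, 0.33, 0.355, 0.38, 0.41, 0.46, 0.55], chosen
after swap-acceptance and ladder-span diagnostics so replicas flow freely
through the transition; 10⁵ recording cycles after 3 × 10⁴ thermalization
per run; swaps every 5 cycles; 8 independent runs pooled for T*ₘ estimates
(reproducibility ≈ 0.5 % s.d. across master seeds) and 4 runs inside the
three-pressure study; 200 kinetic trajectories per pressure with a 2 × 10⁵
cycle cap. The full-scale protocol (50–60 temperatures, 3 × 10⁶ + 10⁷
cycles, 10 runs, 10⁴ trajectories) is wired in
`scripts/reproduce_full_scale.py`.

## Known limitations

* The mirror degeneracy discussed above is intrinsic to distance-only
  potentials; the enantiomer-aware criterion treats it, not cures it.
* WHAM normalizers are computed on binned energies; per-sample reweighting
  inherits an O(bin width) bias, negligible at the default bin of one well
  depth for protein-sized energy ranges.
* Monte Carlo cycles are a time proxy, not physical time; only relative
  kinetic comparisons (across pressures, at matched criteria) are
  meaningful.
* The median first-passage time of a small fixture is a noisy statistic;
  cross-pressure comparisons are run with a common threshold, common
  starting pool and paired trajectory seeds, and tested with a bootstrap
  allowance per step.
* Hard-sphere diameter, move amplitude and move mix are not taken from any
  experiment; defaults are typical Cα-model values and all are configurable.
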