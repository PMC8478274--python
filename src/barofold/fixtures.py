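"""Synthetic toy structures and pseudo-pressure series.

Real multi-pressure structure series are scarce, so this module
generates small protein-like chains that exercise every stage of the
pipeline: a Cα backbone with ~3.8 Å virtual bonds, dummy heavy atoms
offset from the Cα so that atomic contact detection is genuinely
distinct from Cα distances, B-factors, and a fixed-column PDB writer
for round-tripping through the parser.

Topologies
----------
``helix``
    An ideal α-helix-like spiral (i, i+4 contacts).
``hairpin``
    Two antiparallel strands 4.6 Å apart joined by a turn bead; the
    cross-strand contacts are carried by side-chain dummies, not Cα.
``compact``
    A solenoid (coil of coils) whose adjacent turns stack at ~5 Å,
    giving a dense long-range contact map — the work-horse fixture for
    folding simulations.

Pressure series mimic the two experimental phenomenologies: an
"add-contacts" mode where mild uniform compression only creates
contacts (lysozyme-like), and a "mixed" mode where one half of the
chain compacts while the other dilates so contacts both appear and
disappear (DHFR-like).  Pairwise Cα RMSDs stay well below 1 Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import build_contact_map
from .structure import Structure, StructureSeries

__all__ = ["ToySpec", "make_toy_structure", "make_pressure_series", "write_pdb"]

BOND = 3.8  # canonical trans Cα–Cα distance (Å)

_TOPOLOGIES = ("helix", "hairpin", "compact")


@dataclass
class ToySpec:
    n_residues: int = 20
    topology: str = "compact"
    atoms_per_residue: int = 3
    perturbation: float = 0.1      # Å, seeded jitter on the backbone
    contact_bias: float = 0.0      # >0 favours gained, <0 favours lost contacts
    seed: int = 0

    def validate(self) -> None:
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues")
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}; pick from {_TOPOLOGIES}")
        if not (1 <= self.atoms_per_residue <= 3):
            raise ValueError("atoms_per_residue must be 1..3")
        if self.perturbation < 0:
            raise ValueError("perturbation amplitude must be >= 0")


def _helix_backbone(n: int) -> np.ndarray:
    # radius/twist of an ideal α-helix; rise chosen so bonds are exactly 3.8 Å
    radius, twist = 2.3, np.deg2rad(100.0)
    chord = 2 * radius * np.sin(twist / 2)
    rise = np.sqrt(BOND**2 - chord**2)
    k = np.arange(n)
    return np.column_stack(
        [radius * np.cos(k * twist), radius * np.sin(k * twist), k * rise]
    )


def _hairpin_backbone(n: int) -> np.ndarray:
    sep = 4.6  # inter-strand Cα distance: outside the hard sphere, inside
    # heavy-atom contact range once side-chain dummies are added
    n1 = (n - 1) // 2
    coords = np.zeros((n, 3))
    for i in range(n1):
        coords[i] = (i * BOND, 0.0, 0.0)
    x_end = (n1 - 1) * BOND
    dx = np.sqrt(BOND**2 - (sep / 2) ** 2)
    coords[n1] = (x_end + dx, sep / 2, 0.0)
    for i in range(n1 + 1, n):
        coords[i] = (x_end - (i - n1 - 1) * BOND, sep, 0.0)
    return coords


def _compact_backbone(n: int) -> np.ndarray:
    # solenoid: 8 beads per turn, 5 Å pitch -> adjacent turns stack in
    # contact, giving a dense long-range map (~1.5 contacts/residue)
    per_turn, pitch = 8, 5.0
    rise = pitch / per_turn
    chord = np.sqrt(BOND**2 - rise**2)
    radius = chord / (2 * np.sin(np.pi / per_turn))
    theta = np.arange(n) * 2 * np.pi / per_turn
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.arange(n) * rise]
    )


def _axis_direction(topology: str) -> np.ndarray:
    # direction along which the dummy side-chain atoms are offset:
    # across the strands for the hairpin, along the stacking axis else
    return np.array([0.0, 1.0, 0.0]) if topology == "hairpin" else np.array([0.0, 0.0, 1.0])


def make_toy_structure(spec: ToySpec) -> Structure:
    """Deterministic-in-seed synthetic structure.

    The Cα trace follows the requested topology with seeded jitter of
    amplitude ``spec.perturbation``; each residue carries up to two
    dummy heavy atoms (CB/CG) offset ±1.4 Å from the Cα so that contact
    detection runs on atoms other than the interaction centres.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    if spec.topology == "helix":
        ca = _helix_backbone(n)
    elif spec.topology == "hairpin":
        ca = _hairpin_backbone(n)
    else:
        ca = _compact_backbone(n)
    if spec.perturbation > 0:
        ca = ca + rng.normal(scale=spec.perturbation / np.sqrt(3), size=ca.shape)

    length = 1.2 if spec.topology == "hairpin" else 1.4
    offset = length * _axis_direction(spec.topology)
    hairpin = spec.topology == "hairpin"
    n1 = (n - 1) // 2
    axyz, aresi, ab, anames = [], [], [], []
    for i in range(n):
        # hairpin side chains point toward the opposite strand
        sign = -1.0 if (hairpin and i > n1) else 1.0
        atom_pos = [ca[i]]
        names = ["CA"]
        if spec.atoms_per_residue >= 2:
            atom_pos.append(ca[i] + sign * offset)
            names.append("CB")
        if spec.atoms_per_residue >= 3 and not hairpin:
            atom_pos.append(ca[i] - offset)
            names.append("CG")
        for p, nm in zip(atom_pos, names):
            axyz.append(p)
            aresi.append(i)
            ab.append(round(10.0 + 0.2 * i + rng.uniform(0, 2), 2))
            anames.append(nm)

    s = Structure(
        ca=ca,
        atom_xyz=np.asarray(axyz, dtype=float),
        atom_resi=np.asarray(aresi, dtype=np.int64),
        atom_b=np.asarray(ab, dtype=float),
        atom_names=anames,
        res_names=["ALA"] * n,
        res_auth_ids=[str(i + 1) for i in range(n)],
        pressure_label=0.001,
        source_id=f"toy-{spec.topology}-{n}-s{spec.seed}",
    )
    s.validate()
    return s


def _rescale(s: Structure, factors: np.ndarray, pressure: float, tag: str) -> Structure:
    """Scale residue positions about the centroid by per-residue factors."""
    centre = s.ca.mean(axis=0)
    ca = centre + (s.ca - centre) * factors[:, None]
    shift = ca - s.ca
    axyz = s.atom_xyz + shift[s.atom_resi]
    return Structure(
        ca=ca,
        atom_xyz=axyz,
        atom_resi=s.atom_resi.copy(),
        atom_b=s.atom_b.copy(),
        atom_names=list(s.atom_names),
        res_names=list(s.res_names),
        res_auth_ids=list(s.res_auth_ids),
        pressure_label=pressure,
        source_id=f"{s.source_id}-{tag}",
    )


def _shifted(s: Structure, shift: np.ndarray, pressure: float, tag: str) -> Structure:
    """Apply a per-residue displacement field to a structure."""
    return Structure(
        ca=s.ca + shift,
        atom_xyz=s.atom_xyz + shift[s.atom_resi],
        atom_resi=s.atom_resi.copy(),
        atom_b=s.atom_b.copy(),
        atom_names=list(s.atom_names),
        res_names=list(s.res_names),
        res_auth_ids=list(s.res_auth_ids),
        pressure_label=pressure,
        source_id=f"{s.source_id}-{tag}",
    )


def _min_pair_distance(s: Structure, shift: np.ndarray, i: int, j: int) -> float:
    ai = s.atom_xyz[s.atom_resi == i] + shift[i]
    aj = s.atom_xyz[s.atom_resi == j] + shift[j]
    return float(np.sqrt(((ai[:, None, :] - aj[None, :, :]) ** 2).sum(-1)).min())


def _add_contact_snapshots(ref: Structure, n_steps: int, gains_per_step: int):
    """Cumulative displacement fields that each gain a few contacts.

    Greedy over near-cutoff residue pairs: move the two residues of the
    closest non-contact pair toward each other just far enough to form
    the contact; keep the displacement only if no existing contact is
    lost.  Yields one (N, 3) shift field per pressure step; each step's
    map is a strict superset of the previous one by construction.
    """
    cm0 = build_contact_map(ref)
    cutoff, min_sep = cm0.cutoff, cm0.min_separation
    n = ref.n_residues
    shift = np.zeros((n, 3))
    candidates = []
    for i in range(n):
        for j in range(i + min_sep, n):
            if (i, j) in cm0.pairs:
                continue
            d = _min_pair_distance(ref, shift, i, j)
            if cutoff < d <= cutoff + 1.2:
                candidates.append((d, i, j))
    candidates.sort()
    prev_pairs = set(cm0.pairs)
    used: set[tuple[int, int]] = set()
    for _ in range(n_steps):
        gained = 0
        for d0, i, j in candidates:
            if gained >= gains_per_step:
                break
            if (i, j) in used:
                continue
            d = _min_pair_distance(ref, shift, i, j)
            if d <= cutoff:
                used.add((i, j))
                continue
            delta = d - (cutoff - 0.05)
            if delta / 2 > 0.6:  # keep every residue displacement sub-Å
                continue
            u = ref.ca[j] + shift[j] - ref.ca[i] - shift[i]
            u = u / np.linalg.norm(u)
            trial = shift.copy()
            # smoothed displacement: sequence neighbours follow at half
            # amplitude so their own contacts deform less
            for k, w in ((i - 1, 0.5), (i, 1.0), (i + 1, 0.5)):
                if 0 <= k < n:
                    trial[k] += u * delta / 2 * w
            for k, w in ((j - 1, 0.5), (j, 1.0), (j + 1, 0.5)):
                if 0 <= k < n:
                    trial[k] -= u * delta / 2 * w
            pairs = build_contact_map(_shifted(ref, trial, 0.0, "trial")).pairs
            if prev_pairs <= pairs and len(pairs) > len(prev_pairs):
                shift = trial
                prev_pairs = pairs
                used.add((i, j))
                gained += 1
        yield shift.copy()


def make_pressure_series(
    spec: ToySpec,
    n_pressures: int = 4,
    mode: str = "add-contacts",
    pressure_step: float = 2.0,
) -> StructureSeries:
    """Pseudo-pressure series built from one toy structure.

    ``add-contacts`` applies small targeted displacements (well below
    1 Å per residue) that pull near-cutoff residue pairs into contact
    without otherwise distorting the fold, so the contact count grows
    monotonically along the series while the geometry — and hence the
    folding landscape away from the new contacts — is essentially
    preserved.  ``mixed`` compresses the first half of the chain while
    dilating the second, so contacts are both gained and lost at the
    top pressure.  All entries stay within sub-Å Cα RMSD of the
    room-pressure reference.
    """
    if n_pressures < 2:
        raise ValueError("need at least 2 pressures")
    if mode not in ("add-contacts", "mixed"):
        raise ValueError("mode must be 'add-contacts' or 'mixed'")
    ref = make_toy_structure(spec)
    n = ref.n_residues
    entries = [ref]
    pressures = [0.001] + [pressure_step * k for k in range(1, n_pressures)]
    if mode == "add-contacts":
        gains = max(1, 2 + int(round(4 * np.clip(spec.contact_bias, 0.0, 1.0))))
        for snap, k in zip(_add_contact_snapshots(ref, n_pressures - 1, gains),
                           range(1, n_pressures)):
            entries.append(_shifted(ref, snap, pressures[k], f"p{k}"))
    else:
        for k in range(1, n_pressures):
            amp = 0.008 * k
            f = np.where(np.arange(n) < n // 2, 1.0 - amp, 1.0 + amp)
            bias = np.clip(spec.contact_bias, -0.5, 0.5)
            f = f * (1.0 - 0.004 * k * bias)
            entries.append(_rescale(ref, f, pressures[k], f"p{k}"))
    if mode == "mixed":
        # dilation amplitude is doubled (bounded) until the top pressure
        # both gains and loses contacts relative to the reference
        ref_map = build_contact_map(ref)
        for attempt in range(4):
            top = build_contact_map(entries[-1])
            if (top.pairs - ref_map.pairs) and (ref_map.pairs - top.pairs):
                break
            amp = 0.008 * (n_pressures - 1) * (2.0 ** (attempt + 1))
            f = np.where(np.arange(n) < n // 2, 1.0 - amp, 1.0 + amp)
            entries[-1] = _rescale(ref, f, pressures[-1], f"p{n_pressures - 1}")
    series = StructureSeries(entries=entries, reference_index=0)
    series.validate()
    return series


def write_pdb(s: Structure) -> str:
    """Serialise a Structure as fixed-column PDB ATOM records.

    Coordinates are written at 0.001 Å and B-factors at 0.01 precision,
    the limits of the format; values outside the fixed fields raise.
    """
    lines = []
    serial = 0
    for k in range(len(s.atom_xyz)):
        serial += 1
        x, y, z = s.atom_xyz[k]
        if not (-999.999 < x < 9999.999 and -999.999 < y < 9999.999 and -999.999 < z < 9999.999):
            raise ValueError(f"coordinate out of PDB field range: {(x, y, z)}")
        ri = int(s.atom_resi[k])
        name = s.atom_names[k]
        padded = f" {name:<3s}" if len(name) < 4 else name
        element = name[0]
        lines.append(
            f"ATOM  {serial:5d} {padded}{'':1s}{s.res_names[ri]:>3s} A"
            f"{ri + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{s.atom_b[k]:6.2f}"
            f"          {element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
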