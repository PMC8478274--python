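"""Protein structure parsing and basic structural metrics.

Reads PDB-format coordinate files into a light-weight per-residue
representation (heavy atoms + Cα), keeping only protein residues, and
provides the standard Cα-level metrics used throughout the package:
radius of gyration, Kabsch RMSD and per-residue B-factor averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Structure",
    "StructureSeries",
    "parse_structure",
    "radius_of_gyration",
    "kabsch_rotation",
    "kabsch_rmsd",
    "residue_bfactors",
]


@dataclass
class Structure:
    """A single protein chain: heavy atoms grouped by residue.

    Coordinates are in Å, B-factors in Å².  Residues are indexed by a
    0-based sequential index in chain order; the author numbering from
    the source file is retained in ``res_auth_ids`` for reporting only.
    """

    ca: np.ndarray                 # (N, 3) Cα coordinates
    atom_xyz: np.ndarray           # (M, 3) heavy-atom coordinates
    atom_resi: np.ndarray          # (M,) sequential residue index per atom
    atom_b: np.ndarray             # (M,) per-atom B-factors
    atom_names: list[str]          # (M,)
    res_names: list[str]           # (N,)
    res_auth_ids: list[str]        # (N,) author numbering, e.g. "42" or "42A"
    pressure_label: float = 0.001  # kbar
    source_id: str = "unknown"

    @property
    def n_residues(self) -> int:
        return len(self.ca)

    def validate(self, min_residues: int = 2) -> None:
        n = self.n_residues
        if n < min_residues:
            raise ValueError(
                f"{self.source_id}: {n} residue(s); at least {min_residues} required"
            )
        if self.atom_xyz.shape != (len(self.atom_resi), 3):
            raise ValueError("atom coordinate/index arrays are inconsistent")
        counts = np.bincount(self.atom_resi, minlength=n)
        if (counts == 0).any():
            raise ValueError("residue without atoms")
        for name in self.atom_names:
            if name.strip().startswith("H") and name.strip() in ("H", "HA", "HB"):
                raise ValueError("hydrogen atoms present; structure must be heavy-atom only")

    def residue_atoms(self, i: int) -> np.ndarray:
        """Heavy-atom coordinates of residue ``i``."""
        return self.atom_xyz[self.atom_resi == i]


@dataclass
class StructureSeries:
    """Structures of one protein solved at increasing pressure.

    ``reference_index`` points at the room-pressure entry.  All entries
    must share the residue count and ordering so that contact maps and
    RMSDs are comparable residue by residue.
    """

    entries: list[Structure] = field(default_factory=list)
    reference_index: int = 0

    def validate(self) -> None:
        if not self.entries:
            raise ValueError("empty structure series")
        n0 = self.entries[0].n_residues
        for s in self.entries:
            if s.n_residues != n0:
                raise ValueError(
                    f"series entries differ in residue count ({s.source_id}: "
                    f"{s.n_residues} vs {n0})"
                )
        pressures = [s.pressure_label for s in self.entries]
        if pressures != sorted(pressures):
            raise ValueError("series entries must be ordered by increasing pressure")
        if not (0 <= self.reference_index < len(self.entries)):
            raise ValueError("reference_index out of range")

    @property
    def reference(self) -> Structure:
        return self.entries[self.reference_index]


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def _is_protein_residue(res: gemmi.Residue) -> bool:
    if res.name in _WATER_NAMES:
        return False
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    # unknown residue names: trust the record type (ATOM = polymer)
    return res.het_flag == "A"


def _select_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; first record on tie
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def parse_structure(
    pdb_text: str,
    model_index: int = 0,
    chain_id: str | None = None,
    pressure_label: float = 0.001,
    source_id: str | None = None,
) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only protein residues are kept: hydrogens, waters and hetero
    compounds (ligands, ions) are removed.  For multi-model (NMR) files
    only ``model_index`` is read.  Alternate locations are resolved to
    the highest-occupancy variant, first record on tie.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file.
    model_index:
        0-based model to read (NMR ensembles deposit several).
    chain_id:
        Chain to extract; default is the first chain containing protein
        residues.
    pressure_label:
        Pressure (kbar) the structure was solved at; metadata only.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    if not (0 <= model_index < len(st)):
        raise ValueError(f"model index {model_index} out of range (file has {len(st)})")
    model = st[model_index]

    chain = None
    if chain_id is None:
        for ch in model:
            if any(_is_protein_residue(r) for r in ch):
                chain = ch
                break
        if chain is None:
            raise ValueError("no protein chain found in model")
    else:
        for ch in model:
            if ch.name == chain_id:
                chain = ch
                break
        if chain is None:
            raise ValueError(f"chain {chain_id!r} not found in model {model_index}")

    ca: list[np.ndarray] = []
    axyz: list[list[float]] = []
    aresi: list[int] = []
    ab: list[float] = []
    anames: list[str] = []
    res_names: list[str] = []
    res_auth: list[str] = []

    for res in chain:
        if not _is_protein_residue(res):
            continue
        # group by atom name to resolve altlocs
        by_name: dict[str, list[gemmi.Atom]] = {}
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            by_name.setdefault(atom.name, []).append(atom)
        if not by_name:
            continue
        ri = len(res_names)
        ca_atom = None
        for name, variants in by_name.items():
            atom = _select_altloc(variants)
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            axyz.append(list(pos))
            aresi.append(ri)
            ab.append(atom.b_iso)
            anames.append(name)
            if name == "CA":
                ca_atom = pos
        if ca_atom is None:
            raise ValueError(
                f"residue {res.name} {res.seqid.num}{res.seqid.icode.strip()} has no Cα atom"
            )
        ca.append(ca_atom)
        res_names.append(res.name)
        res_auth.append(f"{res.seqid.num}{res.seqid.icode.strip()}")

    if not res_names:
        raise ValueError(f"chain {chain.name!r} contains no protein residues")

    s = Structure(
        ca=np.asarray(ca, dtype=float),
        atom_xyz=np.asarray(axyz, dtype=float),
        atom_resi=np.asarray(aresi, dtype=np.int64),
        atom_b=np.asarray(ab, dtype=float),
        atom_names=anames,
        res_names=res_names,
        res_auth_ids=res_auth,
        pressure_label=pressure_label,
        source_id=source_id or (st.name or "unknown"),
    )
    return s


def radius_of_gyration(coords: np.ndarray) -> float:
    """Unweighted radius of gyration: RMS distance from the centroid (Å)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) == 0:
        raise ValueError("need a non-empty (n, 3) coordinate array")
    d = coords - coords.mean(axis=0)
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation superposing ``mobile`` onto ``target``.

    Returns ``(R, t_mobile, t_target)`` such that
    ``(mobile - t_mobile) @ R.T + t_target`` minimises the RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {target.shape}")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    return r, cm, ct


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD (Å) over rigid superpositions (proper rotations only)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need at least 3 paired points for superposition")
    r, ca_, cb_ = kabsch_rotation(a, b)
    moved = (a - ca_) @ r.T + cb_
    d = moved - b
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def residue_bfactors(s: Structure, mode: str = "all") -> np.ndarray:
    """Per-residue mean B-factor (Å²).

    ``mode="all"`` averages over all heavy atoms of each residue;
    ``mode="ca"`` takes the Cα B-factor verbatim.
    """
    if mode not in ("all", "ca"):
        raise ValueError("mode must be 'all' or 'ca'")
    if len(s.atom_b) == 0:
        raise ValueError("structure carries no B-factors")
    n = s.n_residues
    out = np.empty(n)
    for i in range(n):
        mask = s.atom_resi == i
        if mode == "ca":
            sel = [k for k in np.nonzero(mask)[0] if s.atom_names[k] == "CA"]
            if not sel:
                raise ValueError(f"residue {i} has no Cα B-factor")
            out[i] = s.atom_b[sel[0]]
        else:
            out[i] = s.atom_b[mask].mean()
    return out
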