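"""Native contact maps and pressure difference maps.

A native (tertiary) contact is a residue pair (i, j) with sequence
separation |i - j| >= min_separation whose closest heavy-atom distance
in the experimental structure is within the cutoff.  Interaction
distances d_nat, however, are measured between the Cα atoms: contacts
are detected at atomic resolution but the coarse-grained chain only
carries one bead per residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

logger = logging.getLogger(__name__)

__all__ = ["ContactMap", "DifferenceMap", "build_contact_map", "difference_map"]


@dataclass
class ContactMap:
    n_residues: int
    pairs: set[tuple[int, int]]                  # stored with i < j
    d_nat: dict[tuple[int, int], float]          # Cα–Cα native distances (Å)
    cutoff: float = 4.5
    min_separation: int = 4
    pressure_label: float = 0.001

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)

    @property
    def e_pdb(self) -> float:
        """Reduced energy of the native conformation: -(number of contacts)."""
        return -float(len(self.pairs))

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sorted (i, j, d_nat) arrays for numerical kernels."""
        if not self.pairs:
            z = np.zeros(0, dtype=np.int64)
            return z, z.copy(), np.zeros(0)
        order = sorted(self.pairs)
        i = np.array([p[0] for p in order], dtype=np.int64)
        j = np.array([p[1] for p in order], dtype=np.int64)
        d = np.array([self.d_nat[p] for p in order], dtype=float)
        return i, j, d

    def dnat_matrix(self) -> np.ndarray:
        """Dense (N, N) matrix of native distances; -1 where no contact."""
        m = np.full((self.n_residues, self.n_residues), -1.0)
        for (i, j), d in self.d_nat.items():
            m[i, j] = m[j, i] = d
        return m

    def validate(self) -> None:
        for i, j in self.pairs:
            if not (0 <= i < j < self.n_residues):
                raise ValueError(f"malformed pair ({i}, {j})")
            if j - i < self.min_separation:
                raise ValueError(f"pair ({i}, {j}) violates min_separation")
        if set(self.d_nat) != self.pairs:
            raise ValueError("d_nat keys do not match the contact pair set")


@dataclass
class DifferenceMap:
    """Contacts gained/lost at high pressure relative to a reference map."""

    gained: set[tuple[int, int]] = field(default_factory=set)
    lost: set[tuple[int, int]] = field(default_factory=set)
    reference_pressure: float = 0.001
    comparison_pressure: float = 0.001


def build_contact_map(
    s: Structure,
    cutoff: float = 4.5,
    min_separation: int = 4,
) -> ContactMap:
    """Build the native contact map of a structure.

    Pair (i, j) is a contact iff j - i >= min_separation and some
    heavy-atom pair (one atom from each residue) lies within ``cutoff``
    (inclusive).  d_nat is the Cα–Cα distance of the pair.
    """
    s.validate(min_residues=min_separation + 1)
    tree = cKDTree(s.atom_xyz)
    close = tree.query_pairs(r=cutoff, output_type="ndarray")
    pairs: set[tuple[int, int]] = set()
    for a, b in close:
        ri, rj = int(s.atom_resi[a]), int(s.atom_resi[b])
        if ri > rj:
            ri, rj = rj, ri
        if rj - ri >= min_separation:
            pairs.add((ri, rj))
    d_nat = {}
    for i, j in pairs:
        d = float(np.linalg.norm(s.ca[i] - s.ca[j]))
        d_nat[(i, j)] = d
        if not (3.5 <= d <= 15.0):
            logger.warning(
                "contact (%d, %d) has unusual Cα distance %.2f Å in %s",
                i, j, d, s.source_id,
            )
    return ContactMap(
        n_residues=s.n_residues,
        pairs=pairs,
        d_nat=d_nat,
        cutoff=cutoff,
        min_separation=min_separation,
        pressure_label=s.pressure_label,
    )


def difference_map(high: ContactMap, ref: ContactMap) -> DifferenceMap:
    """Contacts present at high pressure minus those at the reference pressure."""
    if high.n_residues != ref.n_residues:
        raise ValueError(
            f"residue counts differ: {high.n_residues} vs {ref.n_residues}"
        )
    if (high.cutoff, high.min_separation) != (ref.cutoff, ref.min_separation):
        raise ValueError("contact maps built with different cutoff conventions")
    return DifferenceMap(
        gained=high.pairs - ref.pairs,
        lost=ref.pairs - high.pairs,
        reference_pressure=ref.pressure_label,
        comparison_pressure=high.pressure_label,
    )
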