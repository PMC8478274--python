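"""Structure-based (Gō-type) interaction model.

Each native contact contributes a truncated harmonic well centred at
the native Cα–Cα distance d_nat:

    u(r) = eps * [((r - d_nat) / a)^2 - 1]   for |r - d_nat| <= a
    u(r) = 0                                 otherwise

The well depth eps = 1 defines the reduced energy unit, so the native
conformation has reduced energy -(number of contacts).  Every
non-bonded bead pair additionally feels a hard-sphere repulsion:
conformations with any such pair closer than the hard-sphere diameter
carry infinite energy and are never accepted.  Native-contact pairs
whose well reaches below the hard-sphere diameter (d_nat - a < sigma)
are exempt from the repulsion inside the well range, so that the
native geometry itself can never be rejected.

The folding coordinate Q of a conformation is the ratio of its reduced
energy to the native energy, Q = E*_sampled / E*_PDB; Q = 1 in the
native minimum and Q ~ 0 for fully unfolded chains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactMap
from .structure import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "OVERLAP",
    "ModelParams",
    "Conformation",
    "pair_energy",
    "total_energy",
    "q_coordinate",
    "native_conformation",
]

#: Sentinel energy of an excluded-volume overlap; such moves are always rejected.
OVERLAP = math.inf


@dataclass
class ModelParams:
    """Interaction parameters of the coarse-grained model.

    epsilon
        Depth of every native-contact well; defines the reduced energy
        (and temperature) unit.  Always 1 in reduced units.
    well_halfwidth_a
        Half-width ``a`` of the truncated harmonic well (Å).
    hardsphere_diameter
        Excluded-volume diameter of the beads (Å); bonded neighbours
        (|i - j| = 1) are exempt.
    bond_lengths
        Fixed virtual-bond lengths (Å), taken from the native Cα trace.
    """

    epsilon: float = 1.0
    well_halfwidth_a: float = 0.6
    hardsphere_diameter: float = 4.0
    bond_lengths: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def validate(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0 < self.well_halfwidth_a < self.hardsphere_diameter):
            raise ValueError("need 0 < well_halfwidth_a < hardsphere_diameter")
        if len(self.bond_lengths) and (self.bond_lengths <= 0).any():
            raise ValueError("bond lengths must be positive")

    @classmethod
    def from_structure(cls, s: Structure, **kwargs) -> "ModelParams":
        bonds = np.linalg.norm(np.diff(s.ca, axis=0), axis=1)
        p = cls(bond_lengths=bonds, **kwargs)
        p.validate()
        return p


@dataclass
class Conformation:
    """State of the bead chain: N positions with fixed virtual bonds."""

    coords: np.ndarray                  # (N, 3)
    energy: float | None = None        # cached reduced energy

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def copy(self) -> "Conformation":
        return Conformation(self.coords.copy(), self.energy)

    def check_bonds(self, bond_lengths: np.ndarray, tol: float = 1e-9) -> None:
        d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        if np.abs(d - bond_lengths).max() > tol:
            raise ValueError("virtual bond lengths violated beyond tolerance")


def pair_energy(r: float, d_nat: float, p: ModelParams) -> float:
    """Truncated harmonic native-contact well (reduced units)."""
    if r <= 0:
        raise ValueError("distance must be positive")
    x = r - d_nat
    a = p.well_halfwidth_a
    if abs(x) <= a:
        return p.epsilon * ((x / a) ** 2 - 1.0)
    return 0.0


def total_energy(c: Conformation, m: ContactMap, p: ModelParams) -> float:
    """Total reduced energy of a conformation, or ``OVERLAP``.

    Sums the native-contact wells over the contact map and applies the
    hard-sphere exclusion to every non-bonded pair; returns ``OVERLAP``
    (+inf) on any excluded-volume violation.
    """
    coords = c.coords
    n = len(coords)
    if n != m.n_residues:
        raise ValueError(f"conformation has {n} beads; contact map expects {m.n_residues}")
    sigma = p.hardsphere_diameter
    a = p.well_halfwidth_a
    dmat = m.dnat_matrix()
    e = 0.0
    for i in range(n - 1):
        d = coords[i + 1:] - coords[i]
        r = np.sqrt((d * d).sum(axis=1))
        for k, rij in enumerate(r):
            j = i + 1 + k
            if j == i + 1:
                continue  # bonded: rigid rod, no interaction
            dn = dmat[i, j]
            if dn > 0:
                if rij < sigma and rij < dn - a:
                    return OVERLAP
                x = rij - dn
                if abs(x) <= a:
                    e += p.epsilon * ((x / a) ** 2 - 1.0)
            elif rij < sigma:
                return OVERLAP
    return e


def q_coordinate(e_sampled: float, e_pdb: float) -> float:
    """Folding coordinate Q = E*_sampled / E*_PDB (dimensionless)."""
    if e_pdb >= 0:
        raise ValueError("native reduced energy must be negative")
    return e_sampled / e_pdb


def native_conformation(s: Structure, m: ContactMap, p: ModelParams) -> Conformation:
    """The native Cα trace as a Conformation, validated against the model.

    Checks that the native geometry does not trip the excluded volume
    (native contacts inside the well range are exempt by construction;
    any other violation indicates an inconsistent hard-sphere diameter)
    and caches the native energy, which equals -(number of contacts).
    """
    c = Conformation(np.array(s.ca, dtype=float))
    e = total_energy(c, m, p)
    if e == OVERLAP:
        raise ValueError(
            "native conformation violates the hard-sphere diameter "
            f"({p.hardsphere_diameter} Å); reduce it for this structure"
        )
    n_exempt = sum(1 for d in m.d_nat.values() if d - p.well_halfwidth_a < p.hardsphere_diameter)
    if n_exempt:
        logger.info(
            "%d native contact(s) reach below the hard-sphere diameter; "
            "the well takes precedence inside its range for those pairs",
            n_exempt,
        )
    c.energy = e
    return c
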