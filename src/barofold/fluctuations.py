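"""Per-residue fluctuations: simulated RMSF and experimental B-factor ratios.

The RMSF of residue i is the root-mean-square deviation of bead i from
its native position over an equilibrium trajectory, after rigid-body
superposition (Kabsch, all Cα, unit weights) of every frame onto the
native reference.  Ratios of profiles at elevated pressure to the
room-pressure profile expose where pressure stiffens or loosens the
chain; experimental per-residue B-factor ratios are the corresponding
crystallographic observable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure import Structure, kabsch_rotation, residue_bfactors

logger = logging.getLogger(__name__)

__all__ = ["RmsfProfile", "rmsf", "pressure_ratio", "bfactor_ratio"]


@dataclass
class RmsfProfile:
    values: np.ndarray                       # per-residue RMSF (Å)
    errors: np.ndarray = field(default_factory=lambda: np.zeros(0))
    temperature: float = float("nan")
    pressure_label: float = 0.001

    def __post_init__(self):
        if len(self.errors) == 0:
            self.errors = np.zeros_like(self.values)
        if (self.values < 0).any():
            raise ValueError("RMSF values must be non-negative")


def _superposed_sq_dev(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """(n_frames, N) squared deviations after per-frame Kabsch superposition."""
    out = np.empty((len(frames), len(reference)))
    for f, coords in enumerate(frames):
        r, cm, ct = kabsch_rotation(coords, reference)
        moved = (coords - cm) @ r.T + ct
        out[f] = ((moved - reference) ** 2).sum(axis=1)
    return out


def rmsf(
    frames: np.ndarray | list[np.ndarray],
    reference: np.ndarray,
    temperature: float = float("nan"),
    pressure_label: float = 0.001,
    n_blocks: int = 5,
) -> RmsfProfile:
    """Per-residue RMSF (Å) of a trajectory about the native reference.

    Every frame is rigid-body superposed onto ``reference`` first, so a
    global rotation/translation of the whole trajectory leaves the
    profile unchanged.  Standard errors come from block averaging over
    ``n_blocks`` contiguous trajectory segments, which discounts the
    serial correlation of Monte Carlo samples.
    """
    frames = np.asarray(frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frames.ndim != 3 or frames.shape[1:] != reference.shape:
        raise ValueError(
            f"frames shape {frames.shape} incompatible with reference {reference.shape}"
        )
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    sq = _superposed_sq_dev(frames, reference)
    values = np.sqrt(sq.mean(axis=0))
    n_blocks = min(n_blocks, len(frames))
    if n_blocks >= 2:
        blocks = np.array_split(sq, n_blocks, axis=0)
        block_rmsf = np.array([np.sqrt(b.mean(axis=0)) for b in blocks])
        errors = block_rmsf.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    else:
        errors = np.zeros_like(values)
    return RmsfProfile(values=values, errors=errors,
                       temperature=temperature, pressure_label=pressure_label)


def pressure_ratio(profile_p: np.ndarray, profile_ref: np.ndarray) -> np.ndarray:
    """Elementwise ratio of a high-pressure profile to the room-pressure one.

    Positions where the reference vanishes yield NaN (flagged, not
    silently dropped).
    """
    p = np.asarray(profile_p, dtype=float)
    ref = np.asarray(profile_ref, dtype=float)
    if p.shape != ref.shape:
        raise ValueError("profiles differ in length")
    out = np.full_like(p, np.nan)
    ok = ref > 0
    out[ok] = p[ok] / ref[ok]
    if (~ok).any():
        logger.warning("%d position(s) with zero reference value", int((~ok).sum()))
    return out


def bfactor_ratio(s_p: Structure, s_ref: Structure, mode: str = "all") -> np.ndarray:
    """Per-residue experimental B-factor ratio, high pressure over reference."""
    if s_p.n_residues != s_ref.n_residues:
        raise ValueError("structures differ in residue count")
    return pressure_ratio(residue_bfactors(s_p, mode), residue_bfactors(s_ref, mode))
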