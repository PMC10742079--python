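"""Chain-shape metrics and the analytical equidistant-bead model.

The analytical model depicts an n-triplet linear peptide as n equal-mass
points at fixed spacing l on a line.  With k = floor(n/2):

* odd n = 2k+1 — the center of mass sits on the central bead, the bead
  distances from it are l, 2l, ..., kl, Ree = 2kl, and (averaging over the
  non-central beads)  Rg²/Ree² = (1/6)(k+1)(2k+1)/(2k)².
* even n = 2k — the closest beads are l/2 from the center of mass,
  Ree = (2k-1)l, and  Rg²/Ree² = (1/12)(2k+1)/(2k-1).

Both branches share the closed form Rg² = (l²/12)·(n+1)n (odd) or
(l²/12)·(n+1)(n-1) (even) and converge to Rg/Ree = 1/sqrt(12) ≈ 0.2887 as
k → ∞, below the ideal-chain value 1/sqrt(6) ≈ 0.408 — the signature of a
rigid rod.  A globular protein of N residues instead follows the empirical
scaling Rg = 0.395·N^(3/5) + 7.257 Å.

Numerical metrics (Rg, Ree, Kabsch superposition RMSD, per-atom RMSF)
operate on the :class:`~hydrashell.core.Trajectory` model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import ConfigError, Frame, InputError, Trajectory

__all__ = [
    "BeadModel",
    "FitSummary",
    "pyramidal_number",
    "bead_ratio_squared",
    "bead_ree",
    "bead_rg",
    "bead_convention_rg",
    "estimate_spacing",
    "globular_rg",
    "radius_of_gyration",
    "end_to_end_distance",
    "superpose",
    "rmsf",
]


@dataclass(frozen=True)
class BeadModel:
    """Equidistant-bead chain: ``n`` triplets at spacing ``l`` (Å)."""

    n_triplets: int
    spacing_l: float = 8.85

    def __post_init__(self) -> None:
        if self.n_triplets < 2:
            raise ConfigError("bead model requires n >= 2")
        if self.spacing_l <= 0:
            raise ConfigError("spacing_l must be positive")

    @property
    def k(self) -> int:
        return self.n_triplets // 2

    @property
    def parity(self) -> str:
        return "odd" if self.n_triplets % 2 else "even"


@dataclass
class FitSummary:
    """Rg/Ree summary of a chain or ensemble."""

    Rg: float
    Ree: float
    per_chain: dict[str, tuple[float, float]] | None = None

    @property
    def ratio(self) -> float:
        return self.Rg / self.Ree if self.Ree > 0 else math.nan


def pyramidal_number(k: int) -> int:
    """Square pyramidal number P_k = sum of the first k squares."""
    if k < 0:
        raise ConfigError("k must be >= 0")
    return k * (k + 1) * (2 * k + 1) // 6


def bead_ratio_squared(model: BeadModel) -> float:
    """Closed-form Rg²/Ree² of the bead chain (odd and even branches)."""
    k = model.k
    if model.parity == "odd":
        if model.n_triplets < 3:
            raise ConfigError("odd branch requires n >= 3")
        return (k + 1) * (2 * k + 1) / (6.0 * (2 * k) ** 2)
    return (2 * k + 1) / (12.0 * (2 * k - 1))


def bead_ree(model: BeadModel) -> float:
    """End-to-end distance of the bead chain: 2kl (odd) or (2k-1)l (even)."""
    k, l = model.k, model.spacing_l
    return (2 * k if model.parity == "odd" else 2 * k - 1) * l


def bead_rg(model: BeadModel) -> float:
    """Closed-form bead-chain Rg: l·sqrt((n+1)n/12) odd, l·sqrt((n+1)(n-1)/12) even."""
    n, l = model.n_triplets, model.spacing_l
    if model.parity == "odd":
        return l * math.sqrt((n + 1) * n / 12.0)
    return l * math.sqrt((n + 1) * (n - 1) / 12.0)


def bead_convention_rg(points: np.ndarray) -> float:
    """Numerical Rg of an ordered bead set under the analytical convention.

    For an odd number of beads the central bead (which sits on the center
    of mass of an equidistant chain) is excluded from the average, matching
    the analytical model's normalisation by the 2k non-central beads;
    distances are still measured from the full-set centroid.  For an even
    count all beads enter.  This is deliberately distinct from
    :func:`radius_of_gyration`, which averages over *all* points.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise InputError("need at least two ordered bead positions")
    center = points.mean(axis=0)
    sel = points
    if len(points) % 2 == 1:
        sel = np.delete(points, len(points) // 2, axis=0)
    d2 = ((sel - center) ** 2).sum(axis=1)
    return float(math.sqrt(d2.mean()))


def estimate_spacing(ree_by_n: dict[int, float]) -> float:
    """Bead spacing l as the least-squares slope of Ree against n.

    For exactly two consecutive n this reduces to the difference of the
    two Ree values.
    """
    if len(ree_by_n) < 2:
        raise InputError("need Ree for at least two chain lengths")
    ns = np.array(sorted(ree_by_n), dtype=float)
    rees = np.array([ree_by_n[int(n)] for n in ns])
    if np.ptp(rees) == 0.0:
        warnings.warn("all Ree values equal; slope is 0", stacklevel=2)
        return 0.0
    slope = np.polyfit(ns, rees, 1)[0]
    return float(slope)


def globular_rg(n_residues: int) -> float:
    """Empirical globular-protein radius of gyration, Rg = 0.395·N^0.6 + 7.257 Å."""
    if n_residues < 1:
        raise ConfigError("residue count must be >= 1")
    return 0.395 * n_residues ** 0.6 + 7.257


# --------------------------------------------------------------------------
# Numerical metrics


def _coords_and_masses(frame, atom_indices, topology):
    coords = frame.coordinates if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    if atom_indices is not None:
        atom_indices = np.asarray(atom_indices, dtype=int)
        coords = coords[atom_indices]
    masses = None
    if topology is not None:
        sel = atom_indices if atom_indices is not None else np.arange(len(topology))
        masses = np.array([topology[i].mass for i in sel])
    return coords, masses


def radius_of_gyration(frame, atom_indices=None, *, topology=None,
                       mass_weighted: bool = False) -> float:
    """Rg of a point subset about its (optionally mass-weighted) centroid.

    With ``mass_weighted=False`` (the default, matching the equal-mass
    polymer-physics convention) every point has unit weight.  Atoms with
    zero mass are excluded from mass-weighted sums.
    """
    coords, masses = _coords_and_masses(frame, atom_indices, topology)
    if len(coords) == 0:
        raise InputError("empty atom subset")
    if mass_weighted:
        if masses is None:
            raise ConfigError("mass weighting requires a topology")
        w = masses.astype(float)
        if w.sum() <= 0:
            raise InputError("total mass is zero")
    else:
        w = np.ones(len(coords))
    w = w / w.sum()
    center = (coords * w[:, None]).sum(axis=0)
    d2 = ((coords - center) ** 2).sum(axis=1)
    return float(math.sqrt((w * d2).sum()))


def end_to_end_distance(traj_or_frame, topology=None, chain: str = "A",
                        terminal_name: str = "CA") -> float:
    """Distance between the first and last ``terminal_name`` atom of a chain.

    Plain Euclidean distance — a chain is treated as whole, never wrapped
    through the periodic boundary.
    """
    if isinstance(traj_or_frame, Trajectory):
        topology = traj_or_frame.topology
        frame = traj_or_frame.frames[0]
    else:
        frame = traj_or_frame
        if topology is None:
            raise ConfigError("a topology is required with a bare frame")
    hits = [(a.residue_seq, a.index) for a in topology
            if a.chain_id == chain and a.name == terminal_name]
    if len(hits) < 2:
        raise InputError(
            f"chain {chain!r} has fewer than two {terminal_name!r} atoms")
    hits.sort()
    first, last = hits[0][1], hits[-1][1]
    d = frame.coordinates[last] - frame.coordinates[first]
    return float(np.linalg.norm(d))


def superpose(mobile: np.ndarray, reference: np.ndarray,
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the RMSD
    is the post-fit residual.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise InputError("superpose needs equally sized coordinate sets")
    if mobile.shape[0] < 3:
        raise InputError("superpose needs at least three atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    fitted = mobile @ rot.T + trans
    rmsd = math.sqrt(float(((fitted - reference) ** 2).sum()) / len(mobile))
    return rot, trans, rmsd


def rmsf(traj: Trajectory, atom_indices, align_to: int = 0,
         align_indices=None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation after rigid alignment.

    Every frame is superposed onto frame ``align_to`` over
    ``align_indices`` (default: the analysed subset itself); the RMSF of
    each analysed atom is the square root of its time-averaged squared
    displacement from its own time-mean position.
    """
    if traj.n_frames < 2:
        raise InputError("RMSF requires at least two frames")
    atom_indices = np.asarray(atom_indices, dtype=int)
    if align_indices is None:
        align_indices = atom_indices
    align_indices = np.asarray(align_indices, dtype=int)
    ref = traj.frames[align_to].coordinates
    aligned = np.empty((traj.n_frames, len(atom_indices), 3))
    for f, frame in enumerate(traj.frames):
        rot, trans, _ = superpose(frame.coordinates[align_indices], ref[align_indices])
        aligned[f] = frame.coordinates[atom_indices] @ rot.T + trans
    mean_pos = aligned.mean(axis=0)
    dev2 = ((aligned - mean_pos) ** 2).sum(axis=2)
    return np.sqrt(dev2.mean(axis=0))
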