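"""Solvent-accessible surface area by the rolling-probe point construction.

For each target atom, points are distributed quasi-uniformly on the sphere
of radius r_vdw + probe (probe default 1.4 Å, a water radius) using a
deterministic golden-spiral lattice; a point is accessible iff it lies
outside every other occluder's expanded sphere, and the atom's SASA is the
accessible fraction of its expanded-sphere area.  This measures the purely
geometric space above the surface into which a water molecule could fit.

Waters and ions are excluded from the occluder set by the caller by
convention (peptide-only surface); hydrogens occlude whenever present in
the topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .core import ConfigError, Frame, InputError, Trajectory

__all__ = [
    "BONDI_RADII",
    "SASAResult",
    "CorrelationResult",
    "golden_spiral_points",
    "atom_sasa",
    "sasa_series",
    "correlate",
]

#: Bondi van der Waals radii (Å), configurable per call.
BONDI_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "H": 1.20, "S": 1.80,
               "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98}

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


@dataclass
class SASAResult:
    """Per-atom and per-residue solvent-accessible areas (Å²)."""

    per_atom: dict[int, float]
    per_residue: dict[tuple[str, int], float]
    probe_radius: float
    n_points: int


@dataclass
class CorrelationResult:
    """Product-moment correlation with its least-squares line."""

    pearson_r: float
    slope: float
    intercept: float
    n: int

    @property
    def r_squared(self) -> float:
        return self.pearson_r ** 2


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (Fibonacci lattice)."""
    if n < 1:
        raise ConfigError("need at least one sphere point")
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii_for(traj_topology, indices, radii_table):
    out = np.empty(len(indices))
    missing = set()
    for k, i in enumerate(indices):
        el = traj_topology[i].element.upper()
        r = radii_table.get(el)
        if r is None:
            missing.add(el)
            r = 0.0
        out[k] = r
    if missing:
        raise InputError(
            f"no van der Waals radius for element(s): {sorted(missing)}")
    return out


def atom_sasa(frame, topology, occluders, targets=None,
              probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_POINTS,
              radii_table: dict[str, float] | None = None) -> SASAResult:
    """Per-atom SASA of ``targets`` against the occluder set.

    ``targets`` defaults to all occluders.  Every target must itself be an
    occluder (an atom cannot be transparent to itself in this
    construction).
    """
    if probe < 0:
        raise ConfigError("probe radius must be non-negative")
    radii_table = radii_table if radii_table is not None else BONDI_RADII
    coords = frame.coordinates if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    occluders = np.asarray(occluders, dtype=int)
    targets = occluders if targets is None else np.asarray(targets, dtype=int)
    if len(occluders) == 0:
        raise InputError("empty occluder set")
    if not set(targets.tolist()) <= set(occluders.tolist()):
        raise InputError("targets must be a subset of the occluders")

    occ_r = _radii_for(topology, occluders, radii_table) + probe
    occ_xyz = coords[occluders]
    tree = cKDTree(occ_xyz)
    occ_pos = {int(a): k for k, a in enumerate(occluders)}
    unit = golden_spiral_points(n_points)

    per_atom: dict[int, float] = {}
    max_r = occ_r.max()
    for a in targets:
        k = occ_pos[int(a)]
        r = occ_r[k]
        center = occ_xyz[k]
        neigh = [j for j in tree.query_ball_point(center, r + max_r)
                 if j != k and np.linalg.norm(occ_xyz[j] - center) < r + occ_r[j]]
        pts = center + r * unit
        if neigh:
            d2 = ((pts[:, None, :] - occ_xyz[neigh][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (occ_r[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[int(a)] = frac * 4.0 * math.pi * r * r

    per_residue: dict[tuple[str, int], float] = {}
    for a, area in per_atom.items():
        atom = topology[a]
        key = (atom.chain_id, atom.residue_seq)
        per_residue[key] = per_residue.get(key, 0.0) + area
    return SASAResult(per_atom=per_atom, per_residue=per_residue,
                      probe_radius=probe, n_points=n_points)


def sasa_series(traj: Trajectory, occluders, targets=None,
                probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_POINTS,
                radii_table: dict[str, float] | None = None) -> SASAResult:
    """Time-averaged per-atom/per-residue SASA over all frames."""
    acc_atom: dict[int, float] = {}
    acc_res: dict[tuple[str, int], float] = {}
    for frame in traj.frames:
        res = atom_sasa(frame, traj.topology, occluders, targets,
                        probe=probe, n_points=n_points, radii_table=radii_table)
        for a, v in res.per_atom.items():
            acc_atom[a] = acc_atom.get(a, 0.0) + v
        for key, v in res.per_residue.items():
            acc_res[key] = acc_res.get(key, 0.0) + v
    nf = traj.n_frames
    return SASAResult(per_atom={a: v / nf for a, v in acc_atom.items()},
                      per_residue={k: v / nf for k, v in acc_res.items()},
                      probe_radius=probe, n_points=n_points)


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation of two per-site value lists with its fit line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise InputError("correlation needs at least three points")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise InputError("zero variance in x or y")
    fit = stats.linregress(x, y)
    return CorrelationResult(pearson_r=float(fit.rvalue), slope=float(fit.slope),
                             intercept=float(fit.intercept), n=len(x))
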