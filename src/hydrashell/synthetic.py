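"""Ground-truth synthetic inputs for the hydration analysis.

Four generators, each emulating one statistical ingredient the analysis
assumes:

* :func:`generate_scaffold` — a rigid, linear, triplet-periodic peptide
  stand-in: equidistant triplet-center beads on an axis and per-residue
  carbonyl-oxygen binding sites on a helix around it, with X/Y/G roles.
* :func:`generate_hydration_trajectory` — structured first-shell hydration
  over that scaffold with a programmable per-role occupancy pattern
  (0-2-1 by default) and site-ligand exchange as a substitution process
  with exponentially distributed sojourn times.
* :func:`generate_ideal_chain` — freely-jointed random walks, the
  reference ensemble with Rg/Ree = 1/sqrt(6).
* :func:`generate_bulk_water` — an ideal-gas water box at a stated number
  density, used for RDF normalisation checks.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seeds give bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AtomRecord,
    ConfigError,
    Frame,
    InputError,
    SiteSelection,
    Trajectory,
    pbc_distances,
    select_carbonyl_sites,
)

__all__ = [
    "ScaffoldConfig",
    "ExchangeConfig",
    "HydrationGroundTruth",
    "generate_scaffold",
    "generate_hydration_trajectory",
    "generate_ideal_chain",
    "generate_bulk_water",
    "sample_slot_schedule",
    "scaffold_sites",
    "BEAD_CHAIN_ID",
    "FIRST_SHELL_DISTANCE",
]

#: Chain id reserved for the triplet-center beads of the scaffold.
BEAD_CHAIN_ID = "Z"

#: Bound waters are placed at the first g(r) maximum of a carbonyl-water RDF.
FIRST_SHELL_DISTANCE = 2.65

#: Number density of liquid water at ambient conditions (molecules/Å^3).
BULK_WATER_DENSITY = 0.0334


@dataclass
class ScaffoldConfig:
    """Geometry of the rigid triplet-periodic scaffold.

    ``spacing_l`` is the distance between adjacent triplet centers; the
    default 8.85 Å is the per-triplet rise obtained from the difference of
    end-to-end distances of consecutive-length peptides.  ``radial_offset``
    is the distance of the carbonyl-O sites from the helix axis.
    """

    n_triplets: int = 10
    spacing_l: float = 8.85
    chains: int = 3
    radial_offset: float = 4.0
    residues_per_turn: float = 10.0
    padding: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_triplets < 1:
            raise ConfigError("n_triplets must be >= 1")
        if self.spacing_l <= 0:
            raise ConfigError("spacing_l must be positive")
        if self.chains < 1:
            raise ConfigError("chains must be >= 1")


@dataclass
class ExchangeConfig:
    """Occupancy pattern and exchange kinetics of the first shell.

    ``pattern`` gives the number of bound-water slots per role (0-2-1 for
    X-Y-G by default).  Each slot's occupant persists for an exponentially
    distributed sojourn with role-specific mean ``mean_sojourn`` (ps) and is
    then replaced by a fresh water (substitution) or, with probability
    ``vacancy_prob``, leaves the slot empty for exactly one frame first.
    """

    pattern: dict[str, int] = field(default_factory=lambda: {"X": 0, "Y": 2, "G": 1})
    mean_sojourn: dict[str, float] = field(
        default_factory=lambda: {"X": 25.0, "Y": 25.68, "G": 81.72})
    frame_interval: float = 1.0
    n_frames: int = 500
    substitution: bool = True
    vacancy_prob: float = 0.0
    bulk_density: float = 0.0
    site_guard: float = 3.6
    cap_half_angle: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if not 0.0 <= self.vacancy_prob <= 1.0:
            raise ConfigError("vacancy_prob must lie in [0, 1]")
        for role, m in self.mean_sojourn.items():
            if m <= 0:
                raise ConfigError(f"mean_sojourn[{role!r}] must be positive")
            if self.frame_interval >= m / 2:
                warnings.warn(
                    f"frame_interval {self.frame_interval} ps >= half the mean sojourn "
                    f"({m} ps) for role {role!r}: discretization bias expected",
                    stacklevel=2,
                )


@dataclass
class HydrationGroundTruth:
    """Everything the generator knows that the analysis must recover."""

    sojourn_ps: dict[str, np.ndarray]          # continuous draws per role
    sojourn_frames: dict[str, np.ndarray]      # discretized (ceil) lengths
    censored: dict[str, np.ndarray]            # clipped by the last frame
    occupancy: np.ndarray                      # (n_sites, n_frames) int counts
    sites: SiteSelection
    per_role_mean_occupancy: dict[str, float]
    pattern: dict[str, int]
    seed: int


def _chain_ids(n: int) -> list[str]:
    letters = [c for c in "ABCDEFGHIJKLMNOPQRSTUVWXY"]
    return letters[:n]


def generate_scaffold(cfg: ScaffoldConfig) -> Trajectory:
    """Build the single-frame rigid scaffold.

    The triplet-center beads lie on the box-centered z axis at exact
    spacing ``l`` (so their end-to-end distance is (n-1)·l); each chain
    contributes three carbonyl-O sites per triplet on a helix of radius
    ``radial_offset``.  X-role oxygens carry three nitrogen blocker
    pseudo-atoms (and G-role oxygens one) emulating the interchain
    hydrogen-bond partner that buries the X site — this reproduces the
    qualitative solvent-exposure ordering Y > G > X without any force
    field.
    """
    n, l = cfg.n_triplets, cfg.spacing_l
    length = (n - 1) * l
    edge = length + l + 2 * cfg.padding
    box = np.diag([edge, edge, edge]).astype(float)
    cx = cy = edge / 2.0
    z0 = (edge - length) / 2.0

    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []

    def add(name, element, resname, resseq, chain, xyz):
        records.append(AtomRecord(
            index=len(records), name=name, element=element,
            mass={"C": 12.011, "O": 15.999, "N": 14.007}[element],
            residue_name=resname, residue_seq=resseq, chain_id=chain,
            is_water=False,
        ))
        coords.append(np.asarray(xyz, dtype=float))

    twist = 2.0 * math.pi / cfg.residues_per_turn
    role_names = {"X": "PRO", "Y": "PRO", "G": "GLY"}
    roles = "XYG"
    for ci, chain in enumerate(_chain_ids(cfg.chains)):
        phase = 2.0 * math.pi * ci / cfg.chains
        for j in range(3 * n):
            triplet, within = divmod(j, 3)
            role = roles[within]
            theta = phase + twist * j
            z = z0 + triplet * l + (within - 1) * (l / 3.0)
            pos = np.array([cx + cfg.radial_offset * math.cos(theta),
                            cy + cfg.radial_offset * math.sin(theta), z])
            add("O", "O", role_names[role], j + 1, chain, pos)
            outward = np.array([math.cos(theta), math.sin(theta), 0.0])
            up = np.array([0.0, 0.0, 1.0])
            side = np.cross(up, outward)
            # Donor-group pseudo-atoms emulating the interchain contact:
            # X-site oxygens accept an interchain hydrogen bond and are
            # essentially buried (four close contacts over the outward
            # hemisphere); G-site oxygens are partially shielded.
            if role == "X":
                dirs = [outward]
                for az in (0.0, 2.0944, 4.1888):  # 120° apart, 70° off axis
                    dirs.append(math.cos(1.2217) * outward
                                + math.sin(1.2217) * (math.cos(az) * side + math.sin(az) * up))
                for d in dirs:
                    d = d / np.linalg.norm(d)
                    add("NB", "N", role_names[role], j + 1, chain, pos + 2.0 * d)
            elif role == "G":
                for az in (1.5708, -1.5708):  # two contacts 65° off the normal
                    d = (math.cos(1.1345) * outward
                         + math.sin(1.1345) * (math.cos(az) * side + math.sin(az) * up))
                    d /= np.linalg.norm(d)
                    add("NB", "N", role_names[role], j + 1, chain, pos + 2.4 * d)

    for i in range(n):
        add("CA", "C", "BEA", i + 1, BEAD_CHAIN_ID,
            np.array([cx, cy, z0 + i * l]))

    frame = Frame(np.vstack(coords), box=box, time=0.0)
    return Trajectory(topology=records, frames=[frame], frame_interval=1.0)


def scaffold_sites(scaffold: Trajectory) -> SiteSelection:
    """Carbonyl-site selection of a scaffold (bead chain excluded)."""
    chains = sorted({a.chain_id for a in scaffold.topology
                     if not a.is_water and a.chain_id != BEAD_CHAIN_ID})
    return select_carbonyl_sites(scaffold, chains=chains)


def sample_slot_schedule(mean_ps: float, n_frames: int, frame_interval: float,
                         vacancy_prob: float, rng: np.random.Generator,
                         ) -> list[tuple[int, int, float]]:
    """Sojourn schedule for one bound-water slot.

    Sojourns are drawn in continuous time (exponential with mean
    ``mean_ps``), discretized to frames by ceiling (minimum one frame), and
    laid end to end; after each departure the slot is left vacant for one
    frame with probability ``vacancy_prob``, otherwise the replacement binds
    immediately (substitution).  Returns ``(start_frame, end_frame,
    drawn_ps)`` triples with ``end`` exclusive and clipped to ``n_frames``.
    """
    out: list[tuple[int, int, float]] = []
    t = 0
    while t < n_frames:
        dur_ps = float(rng.exponential(mean_ps))
        frames = max(1, math.ceil(dur_ps / frame_interval))
        end = min(t + frames, n_frames)
        out.append((t, end, dur_ps))
        t += frames
        if t < n_frames and vacancy_prob > 0.0 and rng.random() < vacancy_prob:
            t += 1
    return out


def _cap_direction(outward: np.ndarray, half_angle_deg: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Uniform unit vector within a spherical cap around ``outward``."""
    cos_max = math.cos(math.radians(half_angle_deg))
    cos_t = rng.uniform(cos_max, 1.0)
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    # orthonormal frame around outward
    a = np.array([0.0, 0.0, 1.0]) if abs(outward[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(outward, a)
    u /= np.linalg.norm(u)
    v = np.cross(outward, u)
    return cos_t * outward + sin_t * (math.cos(phi) * u + math.sin(phi) * v)


def generate_hydration_trajectory(
        scaffold: Trajectory, cfg: ExchangeConfig,
) -> tuple[Trajectory, HydrationGroundTruth]:
    """Attach exchanging first-shell waters (and optional bulk) to a scaffold.

    Each site of role ``r`` carries ``pattern[r]`` slots whose occupants
    follow :func:`sample_slot_schedule`.  A bound water sits at
    2.65 Å from its site oxygen, in a random direction within a cap facing
    away from the scaffold axis, re-drawn until it is at least
    ``site_guard`` from every *other* site oxygen (so distance-based
    counting attributes it unambiguously).  Waters are single oxygen
    points; inactive occupants are parked on a grid in a box corner, far
    from all sites.  Optional bulk waters are placed uniformly at
    ``bulk_density``, rejected within 3.5 Å of any site oxygen, and held
    static.
    """
    rng = np.random.default_rng(cfg.seed)
    sites = scaffold_sites(scaffold)
    if len(sites) == 0:
        raise InputError("scaffold has no carbonyl sites")
    base = scaffold.frames[0]
    box = base.box
    site_pos = base.coordinates[sites.atom_indices()]
    axis_xy = site_pos[:, :2].mean(axis=0)  # scaffold axis is vertical

    n_frames = cfg.n_frames
    # ---- schedules ------------------------------------------------------
    effective_vacancy = cfg.vacancy_prob if cfg.substitution else 1.0
    soj_ps: dict[str, list[float]] = {r: [] for r in cfg.pattern}
    soj_frames: dict[str, list[int]] = {r: [] for r in cfg.pattern}
    censored: dict[str, list[bool]] = {r: [] for r in cfg.pattern}
    events = []  # (site_index, water_local_index, start, end)
    occupancy = np.zeros((len(sites), n_frames), dtype=int)
    water_positions: list[np.ndarray] = []

    for si, site in enumerate(sites):
        role = site.role
        slots = cfg.pattern.get(role, 0)
        if slots == 0:
            continue
        mean = cfg.mean_sojourn.get(role)
        if mean is None:
            raise ConfigError(f"no mean_sojourn for role {role!r}")
        outward3 = np.zeros(3)
        outward3[:2] = site_pos[si, :2] - axis_xy
        norm = np.linalg.norm(outward3)
        outward3 = outward3 / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        others = np.delete(site_pos, si, axis=0)
        for _slot in range(slots):
            for (start, end, dur_ps) in sample_slot_schedule(
                    mean, n_frames, cfg.frame_interval, effective_vacancy, rng):
                # place this occupant once, guarded against other sites
                for _try in range(64):
                    d = _cap_direction(outward3, cfg.cap_half_angle, rng)
                    pos = site_pos[si] + FIRST_SHELL_DISTANCE * d
                    if len(others) == 0 or np.min(
                            np.linalg.norm(others - pos, axis=1)) >= cfg.site_guard:
                        break
                else:
                    pos = site_pos[si] + FIRST_SHELL_DISTANCE * outward3
                wi = len(water_positions)
                water_positions.append(pos)
                events.append((si, wi, start, end))
                occupancy[si, start:end] += 1
                soj_ps[role].append(dur_ps)
                soj_frames[role].append(end - start)
                # end-censored iff the drawn duration was clipped by the
                # last frame (head-censoring cannot occur in the generator)
                censored[role].append(end - start < max(1, math.ceil(dur_ps / cfg.frame_interval)))

    n_exchange = len(water_positions)

    # ---- bulk waters ----------------------------------------------------
    bulk_positions: list[np.ndarray] = []
    if cfg.bulk_density > 0.0:
        if box is None:
            raise ConfigError("bulk water requires a scaffold with a box")
        vol = float(abs(np.linalg.det(box)))
        count = int(round(cfg.bulk_density * vol))
        lo = np.zeros(3)
        hi = np.diagonal(box)
        while len(bulk_positions) < count:
            cand = rng.uniform(lo, hi, size=(max(64, count), 3))
            dmin = np.min(pbc_distances(
                cand[:, None, :] - site_pos[None, :, :], box), axis=1)
            for p in cand[dmin >= 3.5]:
                bulk_positions.append(p)
                if len(bulk_positions) == count:
                    break

    # ---- parking grid for inactive exchange waters ----------------------
    # Inactive occupants must sit somewhere in every frame; a regular grid
    # restricted to points at least 6 Å (minimum image) from every site
    # keeps them invisible to all distance-based analyses.
    if n_exchange:
        if box is not None:
            edge_lens = np.diagonal(box)
            axes = [np.arange(1.5, e - 1.5, 2.5) for e in edge_lens]
        else:
            hi = site_pos.max(axis=0) + 80.0
            lo = site_pos.max(axis=0) + 20.0
            axes = [np.arange(a, b, 2.5) for a, b in zip(lo, hi)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        cand = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        dmin = np.full(len(cand), np.inf)
        for sp in site_pos:
            dmin = np.minimum(dmin, pbc_distances(cand - sp, box))
        safe = cand[dmin >= 6.0]
        if len(safe) < n_exchange:
            raise ConfigError(
                f"only {len(safe)} safe parking spots for {n_exchange} exchange "
                "waters; increase the scaffold padding")
        park = safe[:n_exchange]
    else:
        park = np.zeros((0, 3))

    # ---- topology -------------------------------------------------------
    records = list(scaffold.topology)
    n_scaffold = len(records)
    for w in range(n_exchange + len(bulk_positions)):
        records.append(AtomRecord(
            index=n_scaffold + w, name="OW", element="O", mass=15.999,
            residue_name="HOH", residue_seq=w + 1, chain_id="W", is_water=True,
        ))

    # ---- coordinates ----------------------------------------------------
    base_row = np.vstack([base.coordinates, park.reshape(-1, 3),
                          np.asarray(bulk_positions).reshape(-1, 3)])
    stack = np.repeat(base_row[None, :, :], n_frames, axis=0)
    for (si, wi, start, end) in events:
        stack[start:end, n_scaffold + wi, :] = water_positions[wi]

    frames = [Frame(stack[f], box=box, time=f * cfg.frame_interval)
              for f in range(n_frames)]
    traj = Trajectory(topology=records, frames=frames,
                      frame_interval=cfg.frame_interval)

    per_role_mean = {}
    for role in cfg.pattern:
        rows = sites.positions_of_role(role)
        per_role_mean[role] = float(occupancy[rows].mean()) if len(rows) else float("nan")

    truth = HydrationGroundTruth(
        sojourn_ps={r: np.asarray(v) for r, v in soj_ps.items()},
        sojourn_frames={r: np.asarray(v, dtype=int) for r, v in soj_frames.items()},
        censored={r: np.asarray(v, dtype=bool) for r, v in censored.items()},
        occupancy=occupancy,
        sites=sites,
        per_role_mean_occupancy=per_role_mean,
        pattern=dict(cfg.pattern),
        seed=cfg.seed,
    )
    return traj, truth


def generate_ideal_chain(n_steps: int, n_chains: int, seed: int = 0,
                         chunk: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Per-chain Rg² and Ree² of freely-jointed unit-step 3D random walks.

    A chain of ``n_steps`` steps has ``n_steps + 1`` vertices (the origin
    included); Rg² is taken over the vertices.  Returns ``(rg2, ree2)``
    arrays of length ``n_chains``.
    """
    if n_steps < 1:
        raise ConfigError("n_steps must be >= 1")
    if n_chains < 1:
        raise ConfigError("n_chains must be >= 1")
    rng = np.random.default_rng(seed)
    rg2 = np.empty(n_chains)
    ree2 = np.empty(n_chains)
    done = 0
    while done < n_chains:
        m = min(chunk, n_chains - done)
        steps = rng.normal(size=(m, n_steps, 3))
        steps /= np.linalg.norm(steps, axis=2, keepdims=True)
        pos = np.concatenate([np.zeros((m, 1, 3)), np.cumsum(steps, axis=1)], axis=1)
        ree2[done:done + m] = np.einsum("ij,ij->i", pos[:, -1], pos[:, -1])
        centered = pos - pos.mean(axis=1, keepdims=True)
        rg2[done:done + m] = np.einsum("ijk,ijk->i", centered, centered) / (n_steps + 1)
        done += m
    return rg2, ree2


def generate_bulk_water(box_edge: float, density: float = BULK_WATER_DENSITY,
                        seed: int = 0) -> Trajectory:
    """Uniformly random water oxygens in a cubic box (ideal-gas structure).

    The molecule count is ``round(density * box_edge**3)``.
    """
    if density <= 0.0:
        raise ConfigError("density must be positive")
    if box_edge <= 0.0:
        raise ConfigError("box_edge must be positive")
    count = int(round(density * box_edge ** 3))
    if count > 10_000_000:
        raise ConfigError(f"refusing to generate {count} molecules (> 1e7)")
    if count == 0:
        raise ConfigError("requested density and box yield zero molecules")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box_edge, size=(count, 3))
    records = [AtomRecord(index=i, name="OW", element="O", mass=15.999,
                          residue_name="HOH", residue_seq=i + 1, chain_id="W",
                          is_water=True)
               for i in range(count)]
    frame = Frame(coords, box=np.diag([box_edge] * 3).astype(float))
    return Trajectory(topology=records, frames=[frame], frame_interval=1.0)
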