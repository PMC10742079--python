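"""Structure/trajectory data model, PDB and XYZ I/O, site selection and
periodic-boundary distance arithmetic.

Units: coordinates and distances in Å, times in ps, masses in u.

The data model is deliberately small: an ordered list of :class:`AtomRecord`
(the topology), a list of :class:`Frame` (coordinates + optional triclinic
box), and a :class:`Trajectory` binding the two with a frame interval.
Binding sites (backbone carbonyl oxygens of a triplet-periodic peptide) are
carried as a :class:`SiteSelection`, each site annotated with its X/Y/G role
within the repeat.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "HydraShellError",
    "ConfigError",
    "InputError",
    "PDBParseError",
    "NumericalError",
    "WATER_RESIDUE_NAMES",
    "ATOMIC_MASSES",
    "AtomRecord",
    "Frame",
    "Trajectory",
    "Site",
    "SiteSelection",
    "read_pdb",
    "write_pdb",
    "read_xyz",
    "write_xyz",
    "select_carbonyl_sites",
    "minimum_image_distance",
    "pbc_distances",
    "box_from_lengths_angles",
    "lengths_angles_from_box",
    "half_min_box_extent",
]


class HydraShellError(Exception):
    """Base class for package errors."""


class ConfigError(HydraShellError):
    """Invalid configuration or parameters."""


class InputError(HydraShellError):
    """Invalid or missing input data."""


class PDBParseError(InputError):
    """Malformed PDB content; message names the offending line."""


class NumericalError(HydraShellError):
    """A numerical procedure failed (e.g. a fit did not converge)."""


#: Residue names recognised as water (configurable per call).
WATER_RESIDUE_NAMES = frozenset({"HOH", "SOL", "WAT", "TIP3", "TIP4", "T3P", "T4P", "SPC"})

#: Standard atomic weights (u), keyed by upper-case element symbol.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "HE": 4.0026, "LI": 6.94, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "NE": 20.180,
    "NA": 22.990, "MG": 24.305, "AL": 26.982, "SI": 28.085, "P": 30.974,
    "S": 32.06, "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938,
    "FE": 55.845, "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38,
    "BR": 79.904, "I": 126.904,
}


def _guess_element(atom_name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Protein atom names put the element first ("CA" is an α-carbon, not
    calcium); we therefore prefer the single-letter reading.
    """
    stripped = "".join(ch for ch in atom_name if ch.isalpha())
    if not stripped:
        return ""
    one = stripped[0].upper()
    if one in ATOMIC_MASSES:
        return one
    two = stripped[:2].upper()
    if two in ATOMIC_MASSES:
        return two
    return one


def _mass_for(element: str) -> float:
    m = ATOMIC_MASSES.get(element.upper())
    if m is None:
        warnings.warn(
            f"unknown element {element!r}: mass set to 0 (excluded from mass-weighted sums)",
            stacklevel=3,
        )
        return 0.0
    return m


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the (frame-independent) topology."""

    index: int
    name: str
    element: str
    mass: float
    residue_name: str
    residue_seq: int
    chain_id: str
    is_water: bool = False


@dataclass
class Frame:
    """Coordinates of every topology atom at one instant.

    ``box`` holds three lattice (row) vectors in Å, or ``None`` for a
    non-periodic system.
    """

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise InputError("frame coordinates must have shape (n_atoms, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3, 3):
                raise InputError("box must be three 3-vectors")
            if abs(np.linalg.det(self.box)) <= 0.0:
                raise InputError("box vectors span zero volume")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """An ordered series of frames over one shared topology."""

    topology: list[AtomRecord]
    frames: list[Frame]
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive (ps)")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise InputError(
                    f"frame {i} has {fr.n_atoms} atoms but topology has {n}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_stack(self) -> np.ndarray:
        """All coordinates as one (n_frames, n_atoms, 3) array."""
        return np.stack([fr.coordinates for fr in self.frames])

    def water_oxygen_indices(self) -> np.ndarray:
        """Indices of water oxygen atoms (H atoms are never consulted)."""
        return np.array(
            [a.index for a in self.topology if a.is_water and a.element.upper() == "O"],
            dtype=int,
        )

    def atom_indices(self, *, names: set[str] | None = None,
                     chains: set[str] | None = None,
                     water: bool | None = None) -> np.ndarray:
        out = []
        for a in self.topology:
            if names is not None and a.name not in names:
                continue
            if chains is not None and a.chain_id not in chains:
                continue
            if water is not None and a.is_water != water:
                continue
            out.append(a.index)
        return np.array(out, dtype=int)


@dataclass(frozen=True)
class Site:
    """A water-binding backbone carbonyl oxygen with its triplet role."""

    atom_index: int
    chain_id: str
    residue_seq: int
    role: str


@dataclass
class SiteSelection:
    """Ordered (chain-major, then residue number) list of carbonyl sites."""

    sites: list[Site] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[Site]:
        return iter(self.sites)

    def atom_indices(self) -> np.ndarray:
        return np.array([s.atom_index for s in self.sites], dtype=int)

    def roles(self) -> list[str]:
        return [s.role for s in self.sites]

    def positions_of_role(self, role: str) -> np.ndarray:
        """Positions (into ``sites``) of all sites with the given role."""
        return np.array([i for i, s in enumerate(self.sites) if s.role == role], dtype=int)


# --------------------------------------------------------------------------
# Triclinic cell arithmetic


def box_from_lengths_angles(a: float, b: float, c: float,
                            alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Lattice row vectors from cell lengths (Å) and angles (degrees)."""
    al, be, ga = (math.radians(x) for x in (alpha, beta, gamma))
    ax = a
    bx, by = b * math.cos(ga), b * math.sin(ga)
    cx = c * math.cos(be)
    cy = c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
    cz2 = c * c - cx * cx - cy * cy
    if cz2 <= 0:
        raise InputError("degenerate cell: inconsistent lengths/angles")
    box = np.array([[ax, 0.0, 0.0], [bx, by, 0.0], [cx, cy, math.sqrt(cz2)]])
    box[np.abs(box) < 1e-10] = 0.0
    return box


def lengths_angles_from_box(box: np.ndarray) -> tuple[float, float, float, float, float, float]:
    a, b, c = (np.linalg.norm(v) for v in box)

    def ang(u, v):
        return math.degrees(math.acos(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))

    return a, b, c, ang(box[1], box[2]), ang(box[0], box[2]), ang(box[0], box[1])


def half_min_box_extent(box: np.ndarray) -> float:
    """Half the smallest perpendicular width of the cell.

    Distances up to this value are guaranteed unambiguous under the
    minimum-image convention.
    """
    box = np.asarray(box, dtype=float)
    vol = abs(np.linalg.det(box))
    widths = [
        vol / np.linalg.norm(np.cross(box[(i + 1) % 3], box[(i + 2) % 3]))
        for i in range(3)
    ]
    return 0.5 * min(widths)


_IMAGE_SHIFTS = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)


def _is_orthorhombic(box: np.ndarray) -> bool:
    return bool(np.allclose(box, np.diag(np.diagonal(box))))


def pbc_distances(disp: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image norms of displacement vectors of shape (..., 3).

    Without a box this is the Euclidean norm.  With a box, vectors are
    wrapped into the central cell in fractional coordinates; for a
    non-orthorhombic cell the wrap is followed by an exhaustive search over
    the 27 neighbouring images (correct for any triclinic cell at small
    cost).
    """
    disp = np.asarray(disp, dtype=float)
    if box is None:
        return np.linalg.norm(disp, axis=-1)
    box = np.asarray(box, dtype=float)
    if abs(np.linalg.det(box)) <= 0.0:
        raise InputError("degenerate box (zero volume)")
    frac = disp @ np.linalg.inv(box)
    frac -= np.round(frac)
    wrapped = frac @ box
    if _is_orthorhombic(box):
        return np.linalg.norm(wrapped, axis=-1)
    shifts = _IMAGE_SHIFTS @ box  # (27, 3)
    flat = wrapped.reshape(-1, 3)
    out = np.empty(flat.shape[0])
    step = 100_000  # bound the 27x temporary
    for s in range(0, flat.shape[0], step):
        blk = flat[s:s + step]
        cand = blk[None, :, :] + shifts[:, None, :]
        out[s:s + step] = np.sqrt(np.einsum("kij,kij->ki", cand, cand)).min(axis=0)
    return out.reshape(disp.shape[:-1])


def minimum_image_distance(a: Sequence[float], b: Sequence[float],
                           box: np.ndarray | None = None) -> float:
    """Shortest distance between ``a`` and any periodic image of ``b``."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(pbc_distances(d, box))


# --------------------------------------------------------------------------
# PDB I/O (fixed-width ATOM/HETATM/MODEL/ENDMDL/CRYST1 dialect)


def _parse_atom_line(line: str, lineno: int) -> tuple[str, str, str, int, float, float, float, str]:
    try:
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 77 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from None
    return name, res_name, chain, res_seq, x, y, z, element


def read_pdb(path: str | Path, model_policy: str = "all",
             water_residues: frozenset[str] = WATER_RESIDUE_NAMES,
             frame_interval: float = 1.0) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    Parameters
    ----------
    model_policy:
        ``"all"`` keeps one frame per MODEL record; ``"first"`` stops after
        the first model.  A file without MODEL records yields one frame.
    """
    if model_policy not in ("all", "first"):
        raise ConfigError(f"model_policy must be 'all' or 'first', got {model_policy!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")

    topology: list[AtomRecord] = []
    frames_coords: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    box: np.ndarray | None = None
    in_model = False
    first_model_done = False

    def close_model() -> None:
        nonlocal current, first_model_done
        if current:
            if frames_coords and len(current) != len(frames_coords[0]):
                raise PDBParseError(
                    f"model {len(frames_coords) + 1} has {len(current)} atoms, "
                    f"expected {len(frames_coords[0])}"
                )
            frames_coords.append(current)
            first_model_done = True
        current = []

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "CRYST1":
                try:
                    params = (float(line[6:15]), float(line[15:24]), float(line[24:33]),
                              float(line[33:40]), float(line[40:47]), float(line[47:54]))
                except ValueError as exc:
                    raise PDBParseError(f"malformed CRYST1 record at line {lineno}: {exc}") from None
                # The conventional 1 Å / 90° placeholder cell means "no box".
                if not (params[:3] == (1.0, 1.0, 1.0) and params[3:] == (90.0, 90.0, 90.0)):
                    box = box_from_lengths_angles(*params)
            elif record == "MODEL":
                if first_model_done and model_policy == "first":
                    break
                in_model = True
            elif record == "ENDMDL":
                close_model()
                in_model = False
                if first_model_done and model_policy == "first":
                    break
            elif record in ("ATOM", "HETATM"):
                name, res_name, chain, res_seq, x, y, z, element = _parse_atom_line(line, lineno)
                if not first_model_done:
                    element = element or _guess_element(name)
                    topology.append(AtomRecord(
                        index=len(topology), name=name, element=element,
                        mass=_mass_for(element), residue_name=res_name,
                        residue_seq=res_seq, chain_id=chain,
                        is_water=res_name in water_residues,
                    ))
                current.append((x, y, z))
    close_model()

    if not topology:
        raise InputError(f"{path}: no ATOM/HETATM records found")
    frames = [Frame(np.asarray(coords, dtype=float), box=box, time=i * frame_interval)
              for i, coords in enumerate(frames_coords)]
    return Trajectory(topology=topology, frames=frames, frame_interval=frame_interval)


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a (multi-model) PDB file.

    Coordinates are stored at the format's fixed precision (0.001 Å); a
    read-back therefore reproduces them to three decimals.
    """
    if traj.n_frames == 0:
        raise InputError("cannot write a trajectory with no frames")
    path = Path(path)
    lines: list[str] = []
    box = traj.frames[0].box
    if box is not None:
        a, b, c, al, be, ga = lengths_angles_from_box(box)
        lines.append(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} P 1           1")
    multi = traj.n_frames > 1
    for imodel, frame in enumerate(traj.frames, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:4d}")
        for atom, (x, y, z) in zip(traj.topology, frame.coordinates):
            record = "HETATM" if atom.is_water else "ATOM  "
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            serial = (atom.index + 1) % 100000
            resseq = atom.residue_seq % 10000
            lines.append(
                f"{record}{serial:5d} {name:<4s}{atom.residue_name:>4s} "[:21]
                + f"{atom.chain_id:1s}{resseq:4d}    "
                + f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {atom.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


# --------------------------------------------------------------------------
# XYZ I/O (plain multi-frame element x y z)


def read_xyz(path: str | Path, frame_interval: float = 1.0) -> Trajectory:
    """Read a multi-frame XYZ file (element symbols only; no residue data)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    text = path.read_text().splitlines()
    topology: list[AtomRecord] = []
    frames: list[Frame] = []
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        try:
            n = int(text[i].strip())
        except ValueError:
            raise PDBParseError(f"expected atom count at line {i + 1}")
        block = text[i + 2:i + 2 + n]
        if len(block) < n:
            raise PDBParseError(f"truncated XYZ frame starting at line {i + 1}")
        coords = np.empty((n, 3))
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise PDBParseError(f"malformed XYZ line {i + 3 + j}")
            sym = parts[0]
            coords[j] = [float(p) for p in parts[1:4]]
            if not frames:
                topology.append(AtomRecord(
                    index=j, name=sym, element=sym.upper(), mass=_mass_for(sym.upper()),
                    residue_name="MOL", residue_seq=j + 1, chain_id="A", is_water=False,
                ))
        if len(coords) != len(topology):
            raise PDBParseError(f"frame at line {i + 1} has {n} atoms, expected {len(topology)}")
        frames.append(Frame(coords, time=len(frames) * frame_interval))
        i += 2 + n
    if not topology:
        raise InputError(f"{path}: empty XYZ file")
    return Trajectory(topology=topology, frames=frames, frame_interval=frame_interval)


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    if traj.n_frames == 0:
        raise InputError("cannot write a trajectory with no frames")
    lines: list[str] = []
    for frame in traj.frames:
        lines.append(str(traj.n_atoms))
        lines.append(f"t = {frame.time:.3f} ps")
        for atom, (x, y, z) in zip(traj.topology, frame.coordinates):
            lines.append(f"{atom.element or atom.name:<3s} {x:14.6f} {y:14.6f} {z:14.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Site selection


def select_carbonyl_sites(traj: Trajectory, repeat: str = "XYG",
                          chains: Iterable[str] | None = None) -> SiteSelection:
    """Select backbone carbonyl oxygens (atom name ``O``) as binding sites.

    Roles are assigned from the residue's position within its chain modulo
    the repeat length, anchored at the chain's first residue; ordering is
    chain-major then residue number.  Water residues never contribute sites.
    """
    if not repeat:
        raise ConfigError("repeat pattern must be non-empty")
    requested = set(chains) if chains is not None else None

    by_chain: dict[str, dict[int, dict[str, int]]] = {}
    for atom in traj.topology:
        if atom.is_water:
            continue
        residues = by_chain.setdefault(atom.chain_id, {})
        residues.setdefault(atom.residue_seq, {})[atom.name] = atom.index

    selection = SiteSelection()
    chain_ids = sorted(by_chain) if requested is None else sorted(requested)
    for cid in chain_ids:
        if cid not in by_chain:
            warnings.warn(f"chain {cid!r} not present; selection is empty for it", stacklevel=2)
            continue
        residues = sorted(by_chain[cid].items())
        if len(residues) % len(repeat) != 0:
            warnings.warn(
                f"chain {cid!r} has {len(residues)} residues, not a multiple of "
                f"{len(repeat)}; trailing partial triplet still assigned roles",
                stacklevel=2,
            )
        for pos, (res_seq, atoms) in enumerate(residues):
            oidx = atoms.get("O")
            if oidx is None:
                continue
            selection.sites.append(Site(
                atom_index=oidx, chain_id=cid, residue_seq=res_seq,
                role=repeat[pos % len(repeat)],
            ))
    return selection
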