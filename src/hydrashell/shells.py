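"""Radial distribution functions and first/second hydration-shell analysis.

The first hydration shell of a carbonyl-oxygen site is the set of water
oxygens within the first minimum of the site-water RDF g(r); by default the
computed value 3.225 Å is used for ensemble averages and the slightly
larger 3.5 Å for single-frame (crystal-like) counts.  Two complementary
routes to the same coordination number are provided:

* integrate g(r): the running integral n(r) evaluated at the cutoff
  (:func:`coordination_number`), and
* count directly: per-site, per-frame neighbour counting at the cutoff
  (:func:`site_occupancy`).

The second shell is likewise measured two ways: integrating g(r) between
its first and second minima (:func:`second_shell_integral`), or counting
distinct waters hydrogen-bond-distance from any first-shell water
(:func:`second_shell_hbonded`).  All distances use the minimum-image
convention and only water *oxygen* positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ConfigError,
    InputError,
    SiteSelection,
    Trajectory,
    half_min_box_extent,
    pbc_distances,
)

__all__ = [
    "FIRST_MIN_ENSEMBLE",
    "FIRST_MIN_SINGLE_FRAME",
    "SECOND_MIN_DEFAULT",
    "RDFProfile",
    "ShellExtrema",
    "OccupancySummary",
    "rdf",
    "coordination_number",
    "find_extrema",
    "site_occupancy",
    "second_shell_integral",
    "second_shell_hbonded",
]

#: First g(r) minimum for ensemble-averaged occupancy (liquid water value).
FIRST_MIN_ENSEMBLE = 3.225
#: Slightly larger cutoff used for single-frame / crystal counts.
FIRST_MIN_SINGLE_FRAME = 3.5
#: Default second g(r) minimum bounding the second shell.
SECOND_MIN_DEFAULT = 5.61


@dataclass
class RDFProfile:
    """Binned g(r) with its running integral n(r).

    ``n_cumulative[i]`` is the frame-averaged neighbour count per center
    within ``bin_edges[i + 1]``.
    """

    bin_edges: np.ndarray
    g: np.ndarray
    n_cumulative: np.ndarray
    reference_count: int
    density_used: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ShellExtrema:
    """Positions (Å) of the first two g(r) peaks and minima; absent = None."""

    first_max: float | None = None
    first_min: float | None = None
    second_max: float | None = None
    second_min: float | None = None


@dataclass
class OccupancySummary:
    """Frame-averaged water counts per site and per role."""

    per_site: np.ndarray
    per_role: dict[str, float]
    per_role_excluding_termini: dict[str, float]
    cutoff_used: float
    sites: SiteSelection


def _water_oxygens(traj: Trajectory) -> np.ndarray:
    ow = traj.water_oxygen_indices()
    if len(ow) == 0:
        raise InputError("trajectory contains no water oxygen atoms")
    return ow


def rdf(traj: Trajectory, centers, others, r_max: float = 8.0,
        bin_width: float = 0.05) -> RDFProfile:
    """Radial distribution function of ``others`` around ``centers``.

    g(r) is the pair count per spherical shell divided by the shell volume
    and the number density of the other set (computed per frame from the
    box volume), averaged over frames and centers.  Self pairs (shared
    atom indices) are excluded.
    """
    centers = np.asarray(centers, dtype=int)
    others = np.asarray(others, dtype=int)
    if len(centers) == 0 or len(others) == 0:
        raise InputError("empty center or other set")
    if r_max <= 0 or bin_width <= 0 or bin_width >= r_max:
        raise ConfigError("need 0 < bin_width < r_max")
    box = traj.frames[0].box
    if box is None:
        raise InputError("RDF normalisation requires a periodic box")
    if r_max > half_min_box_extent(box):
        raise ConfigError(
            f"r_max {r_max} Å exceeds half the smallest box extent "
            f"({half_min_box_extent(box):.2f} Å); minimum image is ambiguous")

    n_bins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts = np.zeros(n_bins)
    density_acc = 0.0
    for frame in traj.frames:
        coords = frame.coordinates
        disp = coords[others][None, :, :] - coords[centers][:, None, :]
        dist = pbc_distances(disp, frame.box)
        # exclude self pairs by index
        shared = np.intersect1d(centers, others)
        if len(shared):
            cpos = {a: i for i, a in enumerate(centers)}
            opos = {a: j for j, a in enumerate(others)}
            for a in shared:
                dist[cpos[a], opos[a]] = np.inf
        counts += np.histogram(dist, bins=edges)[0]
        vol = abs(np.linalg.det(frame.box))
        density_acc += len(others) / vol
    n_frames = traj.n_frames
    density = density_acc / n_frames
    per_center = counts / (n_frames * len(centers))
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = per_center / (shell_vol * density)
    n_cum = np.cumsum(per_center)
    return RDFProfile(bin_edges=edges, g=g, n_cumulative=n_cum,
                      reference_count=len(centers), density_used=density)


def coordination_number(profile: RDFProfile, r_cut: float) -> float:
    """n(r) at ``r_cut`` by linear interpolation of the running integral."""
    edges = profile.bin_edges
    if not edges[0] <= r_cut <= edges[-1]:
        raise ConfigError(f"r_cut {r_cut} outside binned range [{edges[0]}, {edges[-1]}]")
    knots = edges[1:]
    return float(np.interp(r_cut, np.concatenate([[edges[0]], knots]),
                           np.concatenate([[0.0], profile.n_cumulative])))


def find_extrema(profile: RDFProfile, smoothing_window: int = 5) -> ShellExtrema:
    """First two peaks and minima of the moving-average-smoothed g(r).

    Extrema are reported at bin centers; fields remain ``None`` when the
    profile has no corresponding interior extremum (e.g. monotone g).
    """
    g = profile.g
    if len(g) < 10:
        raise InputError("profile has fewer than 10 bins")
    w = max(1, int(smoothing_window)) | 1  # odd window
    kernel = np.ones(w) / w
    pad = w // 2
    # edge-replicating pad keeps monotone profiles monotone after smoothing
    padded = np.concatenate([np.repeat(g[:1], pad), g, np.repeat(g[-1:], pad)])
    smooth = np.convolve(padded, kernel, mode="valid")
    centers = profile.bin_centers
    out = ShellExtrema()
    want_max = True
    found: list[float] = []
    for i in range(1, len(smooth) - 1):
        if want_max and smooth[i] > smooth[i - 1] and smooth[i] >= smooth[i + 1]:
            found.append(centers[i])
            want_max = False
        elif not want_max and smooth[i] < smooth[i - 1] and smooth[i] <= smooth[i + 1]:
            found.append(centers[i])
            want_max = True
        if len(found) == 4:
            break
    for attr, val in zip(("first_max", "first_min", "second_max", "second_min"), found):
        setattr(out, attr, float(val))
    return out


def _site_water_counts(traj: Trajectory, sites: SiteSelection,
                       cutoff: float) -> np.ndarray:
    """(n_sites, n_frames) water-oxygen counts within ``cutoff``."""
    ow = _water_oxygens(traj)
    sidx = sites.atom_indices()
    counts = np.empty((len(sites), traj.n_frames), dtype=int)
    for f, frame in enumerate(traj.frames):
        disp = frame.coordinates[ow][None, :, :] - frame.coordinates[sidx][:, None, :]
        dist = pbc_distances(disp, frame.box)
        counts[:, f] = (dist < cutoff).sum(axis=1)
    return counts


def _terminal_mask(sites: SiteSelection, repeat_len: int = 3) -> np.ndarray:
    """Boolean mask of sites NOT in the first or last triplet of their chain."""
    keep = np.ones(len(sites), dtype=bool)
    by_chain: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_chain.setdefault(s.chain_id, []).append(i)
    for rows in by_chain.values():
        rows = sorted(rows, key=lambda i: sites.sites[i].residue_seq)
        keep[rows[:repeat_len]] = False
        keep[rows[-repeat_len:]] = False
    return keep


def _summarise(per_site: np.ndarray, sites: SiteSelection,
               cutoff: float) -> OccupancySummary:
    roles = sites.roles()
    uniq = sorted(set(roles), key="XYG".index) if set(roles) <= set("XYG") else sorted(set(roles))
    keep = _terminal_mask(sites)
    per_role = {}
    per_role_ex = {}
    for r in uniq:
        rows = sites.positions_of_role(r)
        per_role[r] = float(per_site[rows].mean())
        inner = rows[keep[rows]]
        per_role_ex[r] = float(per_site[inner].mean()) if len(inner) else float("nan")
    return OccupancySummary(per_site=per_site, per_role=per_role,
                            per_role_excluding_termini=per_role_ex,
                            cutoff_used=cutoff, sites=sites)


def site_occupancy(traj: Trajectory, sites: SiteSelection,
                   cutoff: float = FIRST_MIN_ENSEMBLE) -> OccupancySummary:
    """Frame-averaged first-shell water count per site and per role.

    Direct-count route: per frame and site, the number of water oxygens
    within ``cutoff`` by minimum image.  Per-role averages are reported
    both over all sites and excluding each chain's terminal triplets
    (chain-end effects).
    """
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    counts = _site_water_counts(traj, sites, cutoff)
    return _summarise(counts.mean(axis=1), sites, cutoff)


def second_shell_integral(profile: RDFProfile, r_min1: float = FIRST_MIN_ENSEMBLE,
                          r_min2: float = SECOND_MIN_DEFAULT) -> float:
    """Second-shell population by integrating g(r) between its two minima."""
    if not r_min1 < r_min2:
        raise ConfigError("need r_min1 < r_min2")
    return coordination_number(profile, r_min2) - coordination_number(profile, r_min1)


def second_shell_hbonded(traj: Trajectory, sites: SiteSelection,
                         cutoff: float = FIRST_MIN_ENSEMBLE) -> OccupancySummary:
    """Second-shell waters hydrogen-bonded to the first shell.

    Per frame and site: identify the first-shell water oxygens (within
    ``cutoff`` of the site oxygen), then count *distinct* other water
    oxygens within ``cutoff`` of any of them.  A water bonded to two
    first-shell ligands of the same site counts once (the second layer is
    a population, not a bond count); a site with an empty first shell
    contributes zero that frame.
    """
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    ow = _water_oxygens(traj)
    sidx = sites.atom_indices()
    sums = np.zeros(len(sites))
    for frame in traj.frames:
        wcoords = frame.coordinates[ow]
        disp = wcoords[None, :, :] - frame.coordinates[sidx][:, None, :]
        dist = pbc_distances(disp, frame.box)
        first = dist < cutoff
        for si in range(len(sites)):
            fs = np.nonzero(first[si])[0]
            if len(fs) == 0:
                continue
            dd = pbc_distances(
                wcoords[None, :, :] - wcoords[fs][:, None, :], frame.box)
            near = (dd < cutoff).any(axis=0)
            near[fs] = False  # the first shell itself is not the second
            sums[si] += int(near.sum())
    return _summarise(sums / traj.n_frames, sites, cutoff)
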