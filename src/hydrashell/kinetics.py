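"""Water residence-time kinetics at carbonyl binding sites.

A water is "at" a site while its oxygen lies within a cutoff (default
3.5 Å) of the site's carbonyl oxygen; hydrogen positions are never
consulted (they interchange by libration without the oxygen leaving).  A
binding episode (sojourn) tolerates single-frame absences: if the water
leaves for exactly one saved frame and returns in the next, the episode is
not discontinued, and the bridged frame counts toward its duration.  Only
an absence of two or more frames ends the sojourn.  The grace window is
applied per gap, so successive single-frame gaps are each bridged.

The sojourn durations are either averaged directly (<τ>) or binned into a
temporal correlation function f(t) and fitted to A·exp(−t/<τ>); for
exponentially distributed sojourns both routes estimate the same <τ>.
Sojourns touching either trajectory end are flagged censored and excluded
from distributions by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import (
    ConfigError,
    InputError,
    NumericalError,
    SiteSelection,
    Trajectory,
    pbc_distances,
)

__all__ = [
    "RESIDENCE_CUTOFF",
    "OccupancyTrace",
    "Sojourn",
    "SojournSet",
    "ExpFit",
    "occupancy_trace",
    "sojourns",
    "pool_durations",
    "residence_histogram",
    "fit_exponential",
    "mean_residence",
    "substitution_fraction",
]

#: Site cutoff for residence analysis (single-frame value, per convention).
RESIDENCE_CUTOFF = 3.5


@dataclass
class OccupancyTrace:
    """Per-site, per-frame identity sets of bound water oxygens."""

    identities: list[list[frozenset[int]]]  # [site][frame] -> water atom indices
    sites: SiteSelection
    frame_interval: float
    cutoff_used: float

    @property
    def n_frames(self) -> int:
        return len(self.identities[0]) if self.identities else 0

    def counts(self) -> np.ndarray:
        """(n_sites, n_frames) occupant counts."""
        return np.array([[len(s) for s in site] for site in self.identities], dtype=int)


@dataclass(frozen=True)
class Sojourn:
    water_index: int
    start_frame: int
    n_frames: int
    censored: bool

    def duration(self, frame_interval: float) -> float:
        return self.n_frames * frame_interval


@dataclass
class SojournSet:
    """Binding episodes of one site (durations in ps)."""

    durations: np.ndarray
    censored_head: int
    censored_tail: int
    episodes: list[Sojourn] = field(default_factory=list)

    @property
    def n_uncensored(self) -> int:
        return len(self.durations)


def occupancy_trace(traj: Trajectory, sites: SiteSelection,
                    cutoff: float = RESIDENCE_CUTOFF) -> OccupancyTrace:
    """Identify the bound-water set of every site in every frame."""
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    ow = traj.water_oxygen_indices()
    if len(ow) == 0:
        raise InputError("trajectory contains no water oxygen atoms")
    sidx = sites.atom_indices()
    identities: list[list[frozenset[int]]] = [[] for _ in range(len(sites))]
    for frame in traj.frames:
        disp = frame.coordinates[ow][None, :, :] - frame.coordinates[sidx][:, None, :]
        within = pbc_distances(disp, frame.box) < cutoff
        for si in range(len(sites)):
            identities[si].append(frozenset(int(ow[j]) for j in np.nonzero(within[si])[0]))
    return OccupancyTrace(identities=identities, sites=sites,
                          frame_interval=traj.frame_interval, cutoff_used=cutoff)


def _bridged_runs(present_frames: np.ndarray, grace: int) -> list[tuple[int, int]]:
    """Maximal presence runs with gaps of <= ``grace`` frames bridged.

    Each gap is judged individually, so alternating patterns such as
    1,0,1,0,1 merge into a single run under grace=1.  Returns (start,
    end_inclusive) frame pairs.
    """
    runs: list[tuple[int, int]] = []
    start = prev = int(present_frames[0])
    for f in present_frames[1:]:
        f = int(f)
        if f - prev - 1 <= grace:
            prev = f
        else:
            runs.append((start, prev))
            start = prev = f
    runs.append((start, prev))
    return runs


def sojourns(trace: OccupancyTrace, grace: int = 1) -> list[SojournSet]:
    """Extract per-site sojourns, bridging single-frame absences.

    A sojourn's duration is its bridged frame span times the frame
    interval; episodes touching frame 0 or the last frame are censored and
    kept out of ``durations``.
    """
    if grace < 0:
        raise ConfigError("grace must be >= 0")
    n_frames = trace.n_frames
    out: list[SojournSet] = []
    for site_sets in trace.identities:
        frames_by_water: dict[int, list[int]] = {}
        for f, ids in enumerate(site_sets):
            for w in ids:
                frames_by_water.setdefault(w, []).append(f)
        episodes: list[Sojourn] = []
        for w, frames in frames_by_water.items():
            for (a, b) in _bridged_runs(np.asarray(frames), grace):
                episodes.append(Sojourn(
                    water_index=w, start_frame=a, n_frames=b - a + 1,
                    censored=(a == 0) or (b == n_frames - 1)))
        episodes.sort(key=lambda e: (e.start_frame, e.water_index))
        durations = np.array([e.duration(trace.frame_interval)
                              for e in episodes if not e.censored])
        out.append(SojournSet(
            durations=durations,
            censored_head=sum(1 for e in episodes if e.start_frame == 0),
            censored_tail=sum(1 for e in episodes
                              if e.start_frame + e.n_frames == n_frames),
            episodes=episodes,
        ))
    return out


def pool_durations(sojourn_sets: list[SojournSet], sites: SiteSelection,
                   role: str | None = None) -> np.ndarray:
    """Uncensored durations pooled over sites (optionally one role)."""
    rows = range(len(sojourn_sets)) if role is None else sites.positions_of_role(role)
    pools = [sojourn_sets[i].durations for i in rows]
    return np.concatenate(pools) if pools else np.array([])


def residence_histogram(durations: np.ndarray, bin_width: float,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Bin sojourn durations into the temporal correlation function f(t).

    Bins are right-closed, (i·w, (i+1)·w], so a duration equal to a bin
    edge (the common case: durations are multiples of the frame interval)
    falls in the lower bin.  Returns ``(counts, bin_edges)`` over
    [0, max duration], with empty trailing bins trimmed.
    """
    durations = np.asarray(durations, dtype=float)
    if len(durations) == 0:
        raise InputError("no uncensored sojourns to bin")
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")
    idx = np.maximum(np.ceil(durations / bin_width).astype(int) - 1, 0)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    return counts, edges


@dataclass
class ExpFit:
    """Mono-exponential fit f(t) = A·exp(−t/τ)."""

    A: float
    tau_mean: float
    r_squared: float
    bin_width: float
    n_sojourns: int


def fit_exponential(counts: np.ndarray, bin_edges: np.ndarray) -> ExpFit:
    """Least-squares fit of A·exp(−t/τ) to a residence histogram.

    Zero-count bins are excluded: they carry no events, and a semi-log
    exponential fit is only meaningful over occupied bins.
    """
    counts = np.asarray(counts, dtype=float)
    centers = 0.5 * (np.asarray(bin_edges)[:-1] + np.asarray(bin_edges)[1:])
    mask = counts > 0
    if mask.sum() < 3:
        raise InputError("need at least three non-empty bins to fit")
    t, f = centers[mask], counts[mask]
    tau0 = max((t * f).sum() / f.sum(), float(np.diff(bin_edges).mean()))
    try:
        popt, _ = curve_fit(lambda tt, a, tau: a * np.exp(-tt / tau),
                            t, f, p0=(f.max(), tau0), maxfev=10_000)
    except RuntimeError as exc:
        raise NumericalError(f"exponential fit did not converge: {exc}") from exc
    a, tau = (float(v) for v in popt)
    if tau <= 0 or a <= 0:
        raise NumericalError(f"exponential fit returned non-physical A={a}, tau={tau}")
    resid = f - a * np.exp(-t / tau)
    ss_tot = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return ExpFit(A=a, tau_mean=tau, r_squared=r2,
                  bin_width=float(np.diff(bin_edges).mean()), n_sojourns=int(counts.sum()))


def mean_residence(durations: np.ndarray) -> float:
    """Arithmetic mean of uncensored sojourn durations, <τ> (ps)."""
    durations = np.asarray(durations, dtype=float)
    if len(durations) == 0:
        raise InputError("no uncensored sojourns")
    return float(durations.mean())


def substitution_fraction(trace: OccupancyTrace, grace: int = 1,
                          ) -> dict[str, float | None]:
    """Fraction of departures that leave no vacancy, per role.

    A departure is a water identity ending a (bridged) sojourn before the
    last frame.  It counts as a substitution when the site's occupant
    count in the following frame has not dropped below the modal count of
    the site's role, i.e. the leaver was replaced immediately.  Roles with
    no departures report ``None``.
    """
    counts = trace.counts()
    n_frames = trace.n_frames
    roles = trace.sites.roles()
    modal: dict[str, int] = {}
    for r in set(roles):
        rows = trace.sites.positions_of_role(r)
        vals, freq = np.unique(counts[rows], return_counts=True)
        modal[r] = int(vals[np.argmax(freq)])
    events: dict[str, int] = {r: 0 for r in set(roles)}
    kept: dict[str, int] = {r: 0 for r in set(roles)}
    for si, sset in enumerate(sojourns(trace, grace=grace)):
        role = roles[si]
        for e in sset.episodes:
            end = e.start_frame + e.n_frames - 1
            if end >= n_frames - 1:
                continue
            events[role] += 1
            if counts[si, end + 1] >= modal[role]:
                kept[role] += 1
    return {r: (kept[r] / events[r] if events[r] else None) for r in events}
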