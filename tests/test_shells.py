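"""RDF, coordination numbers, extrema, first- and second-shell occupancy."""

import itertools

import numpy as np
import pytest

from hydrashell.core import ConfigError, Frame, Trajectory, minimum_image_distance
from hydrashell.shells import (
    RDFProfile,
    coordination_number,
    find_extrema,
    rdf,
    second_shell_hbonded,
    second_shell_integral,
    site_occupancy,
)
from hydrashell.synthetic import (
    ExchangeConfig,
    ScaffoldConfig,
    generate_bulk_water,
    generate_hydration_trajectory,
    generate_scaffold,
)

from conftest import make_atom, make_water_traj

RHO = 0.0334


def bulk_multi_frame(n_frames=20, edge=30.0, seed0=100):
    frames, top = [], None
    for s in range(n_frames):
        t = generate_bulk_water(edge, RHO, seed=seed0 + s)
        top = t.topology
        frames.append(t.frames[0])
    return Trajectory(top, frames)


class TestRDF:
    def test_ideal_gas_is_flat(self):
        traj = bulk_multi_frame(40)
        idx = np.arange(traj.n_atoms)
        prof = rdf(traj, idx, idx, r_max=8.0, bin_width=0.1)
        sel = prof.bin_centers >= 2.0
        assert np.abs(prof.g[sel] - 1.0).max() < 0.05

    def test_single_neighbor_step(self):
        traj = make_water_traj([[50.0, 50, 50]], [[[52.6, 50, 50]]],
                               box=np.diag([100.0] * 3))
        prof = rdf(traj, [0], [1], r_max=6.0, bin_width=0.1)
        assert prof.n_cumulative[prof.bin_edges[1:] < 2.6].max() == 0.0
        assert prof.n_cumulative[-1] == 1.0
        assert coordination_number(prof, 3.25) == pytest.approx(1.0)

    def test_matches_brute_force_pair_histogram(self, rng):
        """Per-bin equality with an independently written O(N²) double loop."""
        edge = 12.0
        box = np.diag([edge] * 3)
        n = 40
        coords = rng.uniform(0, edge, (n, 3))
        top = [make_atom(i, "OW", element="O", residue_name="HOH",
                         residue_seq=i + 1, chain_id="W", is_water=True)
               for i in range(n)]
        traj = Trajectory(top, [Frame(coords, box=box)])
        r_max, bw = 5.0, 0.25
        prof = rdf(traj, np.arange(n), np.arange(n), r_max=r_max, bin_width=bw)

        nbins = int(round(r_max / bw))
        counts = np.zeros(nbins)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = minimum_image_distance(coords[i], coords[j], box)
                b = int(d // bw)
                if b < nbins:
                    counts[b] += 1
        per_center = counts / n
        shell = 4.0 / 3.0 * np.pi * ((np.arange(1, nbins + 1) * bw) ** 3
                                     - (np.arange(nbins) * bw) ** 3)
        g_oracle = per_center / (shell * (n / edge ** 3))
        np.testing.assert_allclose(prof.g, g_oracle, atol=1e-10)
        np.testing.assert_allclose(prof.n_cumulative, np.cumsum(per_center), atol=1e-10)

    def test_rmax_beyond_half_box_errors(self):
        traj = bulk_multi_frame(1)
        idx = np.arange(traj.n_atoms)
        with pytest.raises(ConfigError, match="half"):
            rdf(traj, idx, idx, r_max=16.0)


class TestCoordinationNumber:
    def test_ideal_gas_matches_analytic_volume(self):
        traj = bulk_multi_frame(20)
        idx = np.arange(traj.n_atoms)
        prof = rdf(traj, idx, idx, r_max=6.0, bin_width=0.05)
        for r in (3.25, 5.0):
            assert coordination_number(prof, r) == pytest.approx(
                4.0 / 3.0 * np.pi * r ** 3 * RHO, rel=0.02)

    def test_out_of_range_errors(self):
        prof = RDFProfile(np.linspace(0, 5, 11), np.ones(10), np.linspace(0, 1, 10), 1, 0.01)
        with pytest.raises(ConfigError):
            coordination_number(prof, 7.0)

    def test_synthetic_g_site_coordination_is_one(self):
        scaffold = generate_scaffold(ScaffoldConfig(n_triplets=3, chains=3))
        traj, truth = generate_hydration_trajectory(
            scaffold, ExchangeConfig(n_frames=60, seed=21))
        g_sites = truth.sites.atom_indices()[truth.sites.positions_of_role("G")]
        prof = rdf(traj, g_sites, traj.water_oxygen_indices(), r_max=6.0)
        assert coordination_number(prof, 3.225) == pytest.approx(1.0, abs=0.02)


class TestFindExtrema:
    @staticmethod
    def _profile(g, bw=0.05):
        n = len(g)
        edges = np.linspace(0, n * bw, n + 1)
        return RDFProfile(edges, np.asarray(g, dtype=float), np.cumsum(g), 1, 0.03)

    def test_constructed_peak_and_trough(self):
        r = np.arange(0.025, 8.0, 0.05)
        g = (2.5 * np.exp(-((r - 2.65) / 0.25) ** 2)
             + 1.2 * np.exp(-((r - 4.5) / 0.6) ** 2))
        g[r > 6.0] = 1.0
        ext = find_extrema(self._profile(g), smoothing_window=3)
        assert ext.first_max == pytest.approx(2.65, abs=0.06)
        assert ext.first_min == pytest.approx(3.25, abs=0.30)
        assert ext.second_max == pytest.approx(4.5, abs=0.10)
        assert ext.first_max < ext.first_min < ext.second_max

    def test_monotone_profile_has_no_extrema(self):
        g = np.linspace(0, 2, 60)
        ext = find_extrema(self._profile(g))
        assert ext.first_max is None and ext.first_min is None

    def test_agrees_with_exhaustive_scan(self, rng):
        g = 1.0 + 0.5 * np.sin(np.linspace(0, 4 * np.pi, 120)) + rng.normal(0, 0.02, 120)
        prof = self._profile(g)
        w = 5
        ext = find_extrema(prof, smoothing_window=w)
        padded = np.concatenate([np.repeat(g[:1], w // 2), g, np.repeat(g[-1:], w // 2)])
        smooth = np.convolve(padded, np.ones(w) / w, mode="valid")
        centers = prof.bin_centers
        # oracle: first strict local max, then alternate
        seq, want_max = [], True
        for i in range(1, len(smooth) - 1):
            if want_max and smooth[i - 1] < smooth[i] >= smooth[i + 1]:
                seq.append(centers[i]); want_max = False
            elif not want_max and smooth[i - 1] > smooth[i] <= smooth[i + 1]:
                seq.append(centers[i]); want_max = True
            if len(seq) == 4:
                break
        assert [ext.first_max, ext.first_min, ext.second_max, ext.second_min] == \
               pytest.approx(seq)


class TestSiteOccupancy:
    def test_synthetic_pattern_recovered_exactly(self):
        scaffold = generate_scaffold(ScaffoldConfig(n_triplets=3, chains=3))
        traj, truth = generate_hydration_trajectory(
            scaffold, ExchangeConfig(n_frames=50, vacancy_prob=0.0, seed=8))
        occ = site_occupancy(traj, truth.sites, cutoff=3.225)
        assert occ.per_role == {"X": 0.0, "Y": 2.0, "G": 1.0}

    def test_hand_placed_waters_respect_cutoff(self):
        traj = make_water_traj([[0.0, 0, 0]], [[[3.0, 0, 0], [3.4, 0, 0]]])
        occ = site_occupancy(traj, _one_site_selection(), cutoff=3.225)
        assert occ.per_site[0] == 1.0

    def test_monotone_in_cutoff(self):
        scaffold = generate_scaffold(ScaffoldConfig(n_triplets=2, chains=2))
        traj, truth = generate_hydration_trajectory(
            scaffold, ExchangeConfig(n_frames=30, bulk_density=0.005, seed=13))
        means = [site_occupancy(traj, truth.sites, cutoff=c).per_site.mean()
                 for c in (2.8, 3.225, 3.5, 4.5, 6.0)]
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))

    def test_crystal_versus_liquid_contrast(self):
        """Frozen exchange reproduces a constant single-frame count;
        fast exchange with vacancies gives fractional Y occupancy."""
        scaffold = generate_scaffold(ScaffoldConfig(n_triplets=2, chains=1))
        frozen, t_frozen = generate_hydration_trajectory(scaffold, ExchangeConfig(
            mean_sojourn={"X": 1e6, "Y": 1e6, "G": 1e6}, n_frames=40, seed=3))
        counts = t_frozen.occupancy
        assert np.all(counts.std(axis=1) == 0.0)
        single = site_occupancy(
            Trajectory(frozen.topology, [frozen.frames[0]]), t_frozen.sites, 3.5)
        np.testing.assert_allclose(single.per_site, counts[:, 0])

        liquid, t_liq = generate_hydration_trajectory(scaffold, ExchangeConfig(
            mean_sojourn={"X": 25.0, "Y": 8.0, "G": 20.0}, n_frames=600,
            vacancy_prob=0.6, seed=4))
        occ = site_occupancy(liquid, t_liq.sites, 3.225)
        assert 1.5 < occ.per_role["Y"] < 2.0
        assert occ.per_role["X"] == 0.0


def _one_site_selection():
    from hydrashell.core import Site, SiteSelection
    return SiteSelection([Site(atom_index=0, chain_id="A", residue_seq=1, role="G")])


class TestSecondShell:
    def test_ideal_gas_annulus(self):
        traj = bulk_multi_frame(20)
        idx = np.arange(traj.n_atoms)
        prof = rdf(traj, idx, idx, r_max=6.0, bin_width=0.05)
        expect = 4.0 / 3.0 * np.pi * RHO * (5.61 ** 3 - 3.225 ** 3)
        assert second_shell_integral(prof, 3.225, 5.61) == pytest.approx(expect, rel=0.02)

    def test_empty_second_shell_is_zero(self):
        traj = make_water_traj([[50.0, 50, 50]], [[[52.6, 50, 50]]],
                               box=np.diag([100.0] * 3))
        prof = rdf(traj, [0], [1], r_max=6.0, bin_width=0.1)
        assert second_shell_integral(prof, 3.225, 5.61) == 0.0

    def test_integral_matches_brute_force_annulus_count(self, rng):
        edge = 14.0
        box = np.diag([edge] * 3)
        n = 60
        coords = rng.uniform(0, edge, (n, 3))
        top = [make_atom(i, "OW", element="O", residue_name="HOH",
                         residue_seq=i + 1, chain_id="W", is_water=True)
               for i in range(n)]
        traj = Trajectory(top, [Frame(coords, box=box)])
        prof = rdf(traj, np.arange(n), np.arange(n), r_max=6.0, bin_width=0.05)
        r1, r2 = 3.0, 5.5  # on bin edges so interpolation is exact
        brute = np.mean([
            sum(1 for j in range(n)
                if j != i and r1 <= minimum_image_distance(coords[i], coords[j], box) < r2)
            for i in range(n)])
        assert second_shell_integral(prof, r1, r2) == pytest.approx(brute, abs=1e-9)

    def test_x_sites_have_no_second_shell(self):
        scaffold = generate_scaffold(ScaffoldConfig(n_triplets=2, chains=3))
        traj, truth = generate_hydration_trajectory(
            scaffold, ExchangeConfig(n_frames=20, bulk_density=0.01, seed=5))
        ss = second_shell_hbonded(traj, truth.sites, cutoff=3.225)
        assert ss.per_role["X"] == 0.0

    def test_hand_built_two_hop_chain(self):
        # site -> w1 at 2.6 Å -> w2 at 2.8 Å from w1, far from the site
        traj = make_water_traj([[0.0, 0, 0]],
                               [[[2.6, 0, 0], [2.6, 2.8, 0]]])
        ss = second_shell_hbonded(traj, _one_site_selection(), cutoff=3.225)
        first = site_occupancy(traj, _one_site_selection(), cutoff=3.225)
        assert first.per_site[0] == 1.0
        assert ss.per_site[0] == 1.0

    def test_matches_brute_force_two_hop_search(self, rng):
        cutoff = 3.225
        sites_xyz = rng.uniform(4, 10, (3, 3))
        waters = rng.uniform(0, 14, (2, 25, 3))  # 2 frames
        traj = make_water_traj(sites_xyz, waters)
        from hydrashell.core import Site, SiteSelection
        sel = SiteSelection([Site(i, "A", i + 1, "G") for i in range(3)])
        ss = second_shell_hbonded(traj, sel, cutoff=cutoff)
        nw = waters.shape[1]
        expect = np.zeros(3)
        for f in range(2):
            for si in range(3):
                first = {j for j in range(nw)
                         if np.linalg.norm(waters[f, j] - sites_xyz[si]) < cutoff}
                second = {j for j in range(nw) if j not in first
                          and any(np.linalg.norm(waters[f, j] - waters[f, k]) < cutoff
                                  for k in first)}
                expect[si] += len(second)
        np.testing.assert_allclose(ss.per_site, expect / 2.0)


def test_direct_count_equals_rdf_integral_route():
    """The two coordination routes (per-site counting vs n(r) at the
    cutoff) agree on identical input."""
    scaffold = generate_scaffold(ScaffoldConfig(n_triplets=3, chains=3))
    traj, truth = generate_hydration_trajectory(
        scaffold, ExchangeConfig(n_frames=40, bulk_density=0.005, seed=17))
    ow = traj.water_oxygen_indices()
    for role in ("Y", "G"):
        rows = truth.sites.positions_of_role(role)
        centers = truth.sites.atom_indices()[rows]
        prof = rdf(traj, centers, ow, r_max=6.0, bin_width=0.025)
        occ = site_occupancy(traj, truth.sites, cutoff=3.225)
        assert coordination_number(prof, 3.225) == pytest.approx(
            occ.per_site[rows].mean(), abs=0.02)
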