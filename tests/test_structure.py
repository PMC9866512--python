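"""Density profiles, maps, shell partitioning, lateral RDF, transitions."""

import math

import numpy as np
import pytest
from scipy.stats import chi2

from cntwater.structure import (density_map, detect_transition,
                                disk_pair_probabilities, first_peak_height,
                                lateral_rdf, partition_shells, radial_density,
                                RDFCurve)
from cntwater.synthetic import AxialSimSpec, gen_axial
from cntwater.trajectory import (Trajectory, TubeGeometry, WaterSystem,
                                 build_water_system)
from conftest import make_uniform_cylinder


def shell_traj(radius0=5.0, n=60, frames=20, seed=0):
    traj, tube, _ = gen_axial(AxialSimSpec(
        n_molecules=n, n_frames=frames, dt=1.0, mode="fickian", D=0.05,
        shells=((radius0, 0.05, 1.0),), seed=seed))
    return traj, build_water_system(traj), tube


class TestRadialDensity:
    def test_single_shell_occupies_one_bin(self):
        traj, ws, tube = shell_traj()
        prof = radial_density(traj, ws, tube, bin_width=0.5)
        hot = prof.counts > 0.01 * prof.counts.sum()
        centers = prof.centers[hot]
        assert np.all(np.abs(centers - 5.0) < 0.75)

    def test_normalization_identity(self, uniform_cylinder):
        traj, ws, tube = uniform_cylinder
        prof = radial_density(traj, ws, tube)
        mean_count = prof.counts.sum() / traj.n_frames
        assert (prof.density * prof.bin_volumes).sum() == \
            pytest.approx(mean_count, abs=1e-9)

    def test_uniform_fill_is_flat(self):
        traj, ws, tube = make_uniform_cylinder(n_molecules=200, n_frames=150,
                                               seed=5)
        prof = radial_density(traj, ws, tube, bin_width=1.0)
        expected = 200 / (math.pi * tube.radius ** 2 * tube.length)
        per_bin_mean = prof.counts / traj.n_frames
        exp_counts = expected * prof.bin_volumes
        sigma = np.sqrt(exp_counts / traj.n_frames)  # Poisson, frame-averaged
        z = (per_bin_mean - exp_counts) / sigma
        assert np.abs(z).max() < 4.0

    def test_empty_tube_warns(self):
        traj, ws, _ = shell_traj()
        far = TubeGeometry((500, 500, 0), (0, 0, 1), 5.0, (0, 10))
        with pytest.warns(UserWarning, match="empty"):
            prof = radial_density(traj, ws, far)
        assert prof.counts.sum() == 0


class TestDensityMap:
    def test_single_static_molecule_one_bin(self):
        pos = np.array([[[1.05, 2.05, 3.0], [1.05, 2.05, 3.3],
                         [1.05, 2.05, 3.6]]])
        traj = Trajectory(pos, 1.0, np.array(["O", "H", "H"], dtype=object))
        ws = WaterSystem(molecules=[(0, 1, 2)])
        tube = TubeGeometry((0, 0, 0), (0, 0, 1), 6.0, (0, 10))
        dm = density_map(traj, ws, tube)
        assert dm.counts.sum() == 1
        assert (dm.counts > 0).sum() == 1

    def test_totals_match_radial_profile(self, uniform_cylinder):
        traj, ws, tube = uniform_cylinder
        prof = radial_density(traj, ws, tube)
        dm = density_map(traj, ws, tube, bin_width=0.5)
        assert dm.counts.sum() == prof.counts.sum()

    def test_shell_appears_as_ring(self):
        traj, ws, tube = shell_traj(radius0=4.0, n=100, frames=30)
        dm = density_map(traj, ws, tube, bin_width=0.5)
        xc = 0.5 * (dm.xedges[:-1] + dm.xedges[1:])
        yc = 0.5 * (dm.yedges[:-1] + dm.yedges[1:])
        rr = np.hypot(xc[:, None], yc[None, :])
        on_ring = dm.counts[(rr > 3.0) & (rr < 5.0)].sum()
        assert on_ring / dm.counts.sum() > 0.95


class TestShellPartition:
    def test_explicit_boundaries_pass_through(self):
        part = partition_shells(boundaries=[0.0, 6.4, 9.8, 15.0])
        assert part.intervals == [(0.0, 6.4), (6.4, 9.8), (9.8, 15.0)]

    def test_idempotent_on_explicit(self):
        part = partition_shells(boundaries=[0.0, 6.4, 9.8, 15.0])
        flat = [part.intervals[0][0]] + [hi for _, hi in part.intervals]
        again = partition_shells(boundaries=flat)
        assert again.intervals == part.intervals

    def test_single_peak_single_shell(self):
        traj, ws, tube = shell_traj()
        prof = radial_density(traj, ws, tube)
        part = partition_shells(prof, radius=tube.radius)
        assert len(part.intervals) == 1
        assert part.intervals[0][0] == 0.0

    def test_two_shells_boundary_near_midpoint(self):
        traj, tube, _ = gen_axial(AxialSimSpec(
            n_molecules=200, n_frames=200, dt=1.0, mode="fickian", D=0.1,
            shells=((3.0, 0.3, 0.5), (8.0, 0.3, 0.5)), seed=2))
        ws = build_water_system(traj)
        prof = radial_density(traj, ws, tube)
        part = partition_shells(prof, radius=tube.radius)
        assert len(part.intervals) == 2
        boundary = part.intervals[0][1]
        assert boundary == pytest.approx(5.5, abs=prof.edges[1] - prof.edges[0])

    def test_shell_assignment(self):
        part = partition_shells(boundaries=[0.0, 5.0, 10.0])
        np.testing.assert_array_equal(
            part.assign(np.array([1.0, 5.0, 9.9, 12.0])), [0, 1, 1, -1])


class TestLateralRDF:
    def test_uniform_disk_statistically_flat(self):
        """Chi-square against g = 1 with across-frame empirical variance
        (pair counts within a frame share points, so they are
        overdispersed relative to Poisson)."""
        from scipy.spatial.distance import pdist
        rng = np.random.default_rng(3)
        R, n, F = 10.0, 100, 80
        edges = np.arange(0, 2 * R + 0.2, 0.2)
        p = disk_pair_probabilities(edges, R)
        per_frame = np.empty((F, edges.size - 1))
        for f in range(F):
            r = R * np.sqrt(rng.random(n))
            th = rng.uniform(0, 2 * math.pi, n)
            pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
            per_frame[f], _ = np.histogram(pdist(pts), bins=edges)
        exp = n * (n - 1) / 2 * p
        sel = exp > 20
        se = per_frame.std(axis=0, ddof=1) / math.sqrt(F)
        stat = (((per_frame.mean(axis=0) - exp)[sel] / se[sel]) ** 2).sum()
        assert stat < chi2.ppf(0.99, int(sel.sum()))

    def test_uniform_fill_g_near_one(self):
        traj, ws, tube = make_uniform_cylinder(n_molecules=150, n_frames=80,
                                               seed=11)
        curve = lateral_rdf(traj, ws, tube, bin_width=0.5)
        sel = curve.expected > 200
        assert np.abs(curve.g[sel] - 1).max() < 0.2

    def test_square_lattice_first_peak_at_spacing(self):
        xs = np.arange(-4.5, 5.0, 3.0)
        pts = np.array([(x, y) for x in xs for y in xs])
        n = len(pts)
        pos = np.zeros((1, 3 * n, 3))
        pos[0, 0::3, :2] = pts
        pos[0, 1::3] = pos[0, 0::3] + [0, 0, 0.3]
        pos[0, 2::3] = pos[0, 0::3] + [0, 0, 0.6]
        traj = Trajectory(pos, 1.0, np.array(["O", "H", "H"] * n,
                                             dtype=object))
        ws = WaterSystem(molecules=[(3 * k, 3 * k + 1, 3 * k + 2)
                                    for k in range(n)])
        tube = TubeGeometry((0, 0, 0), (0, 0, 1), 8.0, (-5, 5))
        curve = lateral_rdf(traj, ws, tube, bin_width=0.05, r_max=8.0)
        first = curve.centers[np.flatnonzero(curve.pair_counts > 0)[0]]
        assert abs(first - 3.0) < 0.05

    def test_two_molecules_single_bin(self):
        pos = np.zeros((1, 6, 3))
        pos[0, 3, 0] = 2.8
        pos[0, 1::3] = pos[0, 0::3] + [0, 0, 0.3]
        pos[0, 2::3] = pos[0, 0::3] + [0, 0, 0.6]
        traj = Trajectory(pos, 1.0, np.array(["O", "H", "H"] * 2,
                                             dtype=object))
        ws = WaterSystem(molecules=[(0, 1, 2), (3, 4, 5)])
        tube = TubeGeometry((0, 0, 0), (0, 0, 1), 5.0, (-3, 3))
        curve = lateral_rdf(traj, ws, tube, bin_width=0.05, r_max=5.0)
        occupied = np.flatnonzero(curve.pair_counts)
        assert len(occupied) == 1
        assert abs(curve.centers[occupied[0]] - 2.8) < 0.05

    def test_mc_normalization_matches_analytic(self):
        edges = np.arange(0, 20.2, 0.2)
        pa = disk_pair_probabilities(edges, 10.0, "analytic")
        pm = disk_pair_probabilities(edges, 10.0, "mc", n_mc=200_000, seed=0)
        assert pa.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.abs(pa - pm).max() < 0.002


class TestTransition:
    def test_gentle_decay_no_transition(self):
        heights = 3.0 * 0.95 ** np.arange(6)
        assert detect_transition(np.arange(250, 310, 10), heights, 0.15) is None

    def test_sharp_drop_interval(self):
        res = detect_transition([250, 260, 270, 280], [3.0, 2.9, 1.8, 1.7],
                                0.15)
        assert res is not None
        (lo, hi), drop = res
        assert (lo, hi) == (260.0, 270.0)
        assert drop == pytest.approx((2.9 - 1.8) / 2.9)

    def test_generator_placed_step_recovered(self):
        rng = np.random.default_rng(0)
        T = np.arange(200, 340, 10.0)
        heights = np.where(T < 275, 3.0, 1.9) * (1 + 0.01 * rng.normal(size=T.size))
        res = detect_transition(T, heights, 0.15)
        assert res is not None
        assert res[0] == (270.0, 280.0)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            detect_transition([260, 250, 270], [3, 2, 1], 0.15)

    def test_first_peak_height_short_range(self):
        centers = np.arange(0.025, 8.0, 0.05)
        g = np.ones_like(centers)
        g[np.abs(centers - 2.8) < 0.1] = 3.0
        g[np.abs(centers - 5.0) < 0.1] = 5.0  # beyond the 3.5 Å readout
        curve = RDFCurve(centers=centers, g=g, pair_counts=g, expected=g)
        assert 2.0 < first_peak_height(curve) <= 3.0
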