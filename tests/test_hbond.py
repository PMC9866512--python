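"""Hydrogen-bond detection, autocorrelation, lifetimes."""

import math

import numpy as np
import pytest

from cntwater.hbond import (BiexpFit, HBACFCurve, HBondCriteria, HBondSeries,
                            detect_hbonds, fit_biexp, hbacf, hbond_series,
                            mean_hbonds_per_molecule, per_shell_lifetime)
from cntwater.structure import partition_shells
from cntwater.synthetic import (BondProcessSpec, gen_bond_process,
                                gen_water_config, hbond_dimer)
from cntwater.trajectory import TubeGeometry, build_water_system
from conftest import brute_force_hbonds, random_water_box

WIDE_TUBE = TubeGeometry((0, 0, 0), (0, 0, 1), 30.0, (-30, 30))


class TestDetect:
    @pytest.mark.parametrize("roo,angle,n_expected", [
        (2.9, 5.0, 1),     # inside both cutoffs
        (3.6, 0.0, 0),     # distance excluded
        (3.50, 30.0, 1),   # inclusive boundary in both criteria
        (2.9, 30.5, 0),    # angle excluded just past the cutoff
    ])
    def test_dimer_cases(self, roo, angle, n_expected):
        traj = gen_water_config(hbond_dimer(roo, angle))
        ws = build_water_system(traj)
        bonds = detect_hbonds(traj.positions[0], ws)
        assert len(bonds) == n_expected
        if n_expected:
            assert bonds == {(0, 1)}  # molecule 0 donates

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        crit = HBondCriteria()
        for _ in range(8):
            placements = random_water_box(60, rng)
            traj = gen_water_config(placements)
            ws = build_water_system(traj)
            fast = detect_hbonds(traj.positions[0], ws, crit)
            slow = brute_force_hbonds(traj.positions[0], ws, crit)
            assert fast == slow

    def test_hydrogen_vertex_convention(self):
        # a perfectly linear O-H...O arrangement passes both conventions
        traj = gen_water_config(hbond_dimer(2.9, 0.0))
        ws = build_water_system(traj)
        crit = HBondCriteria(angle_vertex="hydrogen")
        assert detect_hbonds(traj.positions[0], ws, crit) == {(0, 1)}

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HBondCriteria(r_max=-1)
        with pytest.raises(ValueError):
            HBondCriteria(angle_max=95)


class TestMeanHBonds:
    def test_isolated_molecules_zero(self):
        traj = gen_water_config(hbond_dimer(8.0, 0.0))
        ws = build_water_system(traj)
        assert mean_hbonds_per_molecule(traj, ws, WIDE_TUBE) == 0.0

    def test_static_dimer_one(self):
        traj = gen_water_config(hbond_dimer(2.9, 0.0))
        ws = build_water_system(traj)
        assert mean_hbonds_per_molecule(traj, ws, WIDE_TUBE) == \
            pytest.approx(1.0)

    def test_four_molecule_ring_two(self):
        """Square of molecules, each donating to its clockwise neighbour:
        4 bonds shared among 4 molecules -> 2 bonds per molecule."""
        from cntwater.synthetic import WaterPlacement
        a = 2.9
        corners = [(0, 0, 0), (a, 0, 0), (a, a, 0), (0, a, 0)]
        dirs = [(1, 0, 0), (0, 1, 0), (-1, 0, 0), (0, -1, 0)]
        placements = [WaterPlacement(o=c, h1_dir=d, h2_dir=(0, 0, 1))
                      for c, d in zip(corners, dirs)]
        traj = gen_water_config(placements)
        ws = build_water_system(traj)
        bonds = detect_hbonds(traj.positions[0], ws)
        assert len(bonds) == 4
        assert mean_hbonds_per_molecule(traj, ws, WIDE_TUBE) == \
            pytest.approx(2.0)

    def test_out_of_tube_molecules_excluded(self):
        traj = gen_water_config(hbond_dimer(2.9, 0.0))
        ws = build_water_system(traj)
        narrow = TubeGeometry((0, 0, 0), (0, 0, 1), 1.5, (-5, 5))
        # acceptor at x = 2.9 is outside the 1.5 Å radius: no pair counted
        assert mean_hbonds_per_molecule(traj, ws, narrow) == 0.0


class TestHBACF:
    def test_always_bonded_constant_one(self):
        series = HBondSeries(pairs=[(0, 1)],
                             matrix=np.ones((1, 50), dtype=bool), dt=1.0)
        curve = hbacf(series)
        np.testing.assert_allclose(curve.c, 1.0)

    def test_bond_only_at_frame_zero(self):
        m = np.zeros((1, 30), dtype=bool)
        m[0, 0] = True
        curve = hbacf(HBondSeries(pairs=[(0, 1)], matrix=m, dt=1.0))
        assert curve.c[0] == 1.0
        np.testing.assert_allclose(curve.c[1:], 0.0)

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError):
            hbacf(HBondSeries(pairs=[(0, 1)],
                              matrix=np.zeros((1, 10), dtype=bool), dt=1.0))

    def test_c_zero_is_one_and_nonnegative(self):
        series, _ = gen_bond_process(BondProcessSpec(
            n_pairs=500, a1=0.5, tau1=1.0, tau2=4.0, seed=4))
        curve = hbacf(series)
        assert curve.c[0] == 1.0
        assert (curve.c >= 0).all()

    def test_matches_generator_closed_form_within_3_sigma(self):
        """Pooled estimator vs the exact discrete-time expectation; per-lag
        σ from the spread over independent pair blocks."""
        from cntwater.synthetic import bond_process_acf
        spec = BondProcessSpec(n_pairs=10_000, a1=0.6, tau1=1.0, tau2=5.0,
                               dt=0.1, n_frames=600, seed=1)
        series, _ = gen_bond_process(spec)
        curve = hbacf(series)
        model = bond_process_acf(spec, np.round(curve.lags / spec.dt))
        n_blocks = 100
        blocks = np.array_split(np.arange(spec.n_pairs), n_blocks)
        estimates = []
        for b in blocks:
            sub = HBondSeries(pairs=[series.pairs[i] for i in b],
                              matrix=series.matrix[b], dt=spec.dt)
            estimates.append(hbacf(sub).c)
        se = np.std(estimates, axis=0, ddof=1) / math.sqrt(n_blocks)
        # lag 0 is the exact identity C(0) = 1 with zero spread
        sel = (curve.c > 0.01) & (curve.lags > 0)
        zmax = np.abs((curve.c - model)[sel] / se[sel]).max()
        assert zmax < 3.0


class TestBiexpFit:
    def test_exact_single_exponential(self):
        t = np.arange(0, 200) * 0.1
        c = np.exp(-t / 2.0)
        fit = fit_biexp(HBACFCurve(lags=t, c=c, counts=np.full(t.size, 1e4)))
        assert fit.converged
        assert fit.tau_hb == pytest.approx(2.0, abs=0.05)

    def test_noiseless_biexponential_tau_hb(self):
        t = np.arange(0, 600) * 0.1
        c = 0.6 * np.exp(-t) + 0.4 * np.exp(-t / 5.0)
        fit = fit_biexp(HBACFCurve(lags=t, c=c, counts=np.full(t.size, 1e4)))
        assert fit.tau_hb == pytest.approx(2.6, abs=1e-3)
        assert fit.a1 == pytest.approx(0.6, abs=1e-3)
        assert fit.tau1 <= fit.tau2

    def test_parameter_recovery_under_sampling_noise(self):
        devs = []
        for seed in range(20):
            series, _ = gen_bond_process(BondProcessSpec(
                n_pairs=10_000, a1=0.6, tau1=1.0, tau2=5.0, dt=0.1,
                n_frames=600, seed=seed))
            fit = fit_biexp(hbacf(series))
            devs.append((fit.a1, fit.tau1, fit.tau2))
        devs = np.array(devs)
        assert abs(devs[:, 0].mean() / 0.6 - 1) < 0.10
        assert abs(devs[:, 1].mean() / 1.0 - 1) < 0.10
        assert abs(devs[:, 2].mean() / 5.0 - 1) < 0.10

    def test_tau_hb_invariant_under_component_swap(self):
        a1, t1, t2 = 0.3, 0.8, 4.0
        assert a1 * t1 + (1 - a1) * t2 == pytest.approx(
            (1 - a1) * t2 + a1 * t1)
        t = np.arange(0, 600) * 0.1
        c = a1 * np.exp(-t / t1) + (1 - a1) * np.exp(-t / t2)
        fit = fit_biexp(HBACFCurve(lags=t, c=c, counts=np.full(t.size, 1e4)))
        # canonical ordering reports the swapped parameterisation
        assert fit.tau1 <= fit.tau2
        assert fit.tau_hb == pytest.approx(a1 * t1 + (1 - a1) * t2, abs=1e-3)

    def test_too_few_points_rejected(self):
        t = np.arange(0, 4) * 1.0
        with pytest.raises(ValueError):
            fit_biexp(HBACFCurve(lags=t, c=np.exp(-t),
                                 counts=np.full(4, 100.0)))


class TestPerShell:
    def _static_bond_traj(self, r_donor):
        """Donor/acceptor pair at radius r_donor, bonded every frame."""
        from cntwater.synthetic import WaterPlacement
        placements = [
            WaterPlacement(o=(r_donor, 0, 0), h1_dir=(0, 1, 0),
                           h2_dir=(0, 0, 1)),
            WaterPlacement(o=(r_donor, 2.9, 0), h1_dir=(0, 1, 0),
                           h2_dir=(0, 0, 1)),
        ]
        single = gen_water_config(placements)
        pos = np.repeat(single.positions, 40, axis=0)
        from cntwater.trajectory import Trajectory
        return Trajectory(pos, 1.0, single.labels)

    def test_single_shell_equals_global(self):
        series, _ = gen_bond_process(BondProcessSpec(
            n_pairs=2000, a1=0.6, tau1=1.0, tau2=5.0, dt=0.1, n_frames=600,
            seed=6))
        global_fit = fit_biexp(hbacf(series))
        assert global_fit.tau_hb == pytest.approx(2.6, rel=0.15)

    def test_shell_attribution_and_empty_shell_flagged(self):
        traj = self._static_bond_traj(r_donor=2.0)
        ws = build_water_system(traj)
        tube = TubeGeometry((0, 0, 0), (0, 0, 1), 12.0, (-10, 10))
        shells = partition_shells(boundaries=[0.0, 5.0, 12.0])
        table = per_shell_lifetime(traj, ws, tube, shells, min_events=1)
        assert len(table) == 2
        inner = table.iloc[0]
        outer = table.iloc[1]
        assert inner["n_pairs"] >= 1      # bond attributed to inner shell
        assert outer["n_pairs"] == 0      # empty outer shell
        assert not outer["reliable"]

    def test_sparse_shell_marked_unreliable(self):
        traj = self._static_bond_traj(r_donor=2.0)
        ws = build_water_system(traj)
        tube = TubeGeometry((0, 0, 0), (0, 0, 1), 12.0, (-10, 10))
        shells = partition_shells(boundaries=[0.0, 5.0])
        table = per_shell_lifetime(traj, ws, tube, shells, min_events=10)
        assert not table.iloc[0]["reliable"]
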