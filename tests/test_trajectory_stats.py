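"""Per-frame series, hydrogen-bond occupancy and the water density grid."""

import math

import numpy as np
import pytest
from conftest import brute_force_density, random_rigid_transform

from gpcrprofile import synthetic
from gpcrprofile.structio import Atom, ResidueKey, Structure, Trajectory
from gpcrprofile.trajectory_stats import (
    BULK_WATER_DENSITY,
    GridRegion,
    HBondCriterion,
    hbond_probability,
    high_density_regions,
    min_distance_series,
    rmsd_series,
    select_atoms,
    water_density_grid,
)


def water_box_traj(frames_waters):
    """Trajectory of bare water oxygens from per-frame coordinate arrays."""
    topo = Structure()
    n = len(frames_waters[0])
    for j in range(n):
        topo.add_atom(ResidueKey("W", j + 1, "", "HOH"), Atom("O", "O", np.zeros(3)))
    return Trajectory(topo, [np.asarray(f, float) for f in frames_waters])


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self):
        traj, _ = synthetic.make_hbond_traj(0.0, 8, seed=0)
        fit = np.arange(traj.topology.n_atoms)
        series = rmsd_series(traj, fit)
        assert len(series) == 8
        assert np.abs(series.values).max() < 1e-12

    def test_rigidly_transformed_frames_read_zero(self):
        rng = np.random.default_rng(1)
        base, _ = synthetic.make_hbond_traj(0.0, 1, seed=0)
        x0 = base.frames[0]
        frames = [x0]
        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            frames.append(x0 @ rot.T + trans)
        traj = Trajectory(base.topology, frames)
        series = rmsd_series(traj, np.arange(x0.shape[0]))
        assert np.abs(series.values).max() < 1e-9

    def test_planted_drift_of_report_atoms(self):
        """Report atoms drifting 0.2 A/frame while fit atoms stay put produce
        the analytic per-frame RMSD."""
        topo = Structure()
        rng = np.random.default_rng(2)
        fit_xyz = rng.normal(size=(6, 3))
        rep_xyz = rng.normal(size=(4, 3)) + 10.0
        for i, c in enumerate(fit_xyz):
            topo.add_atom(ResidueKey("R", 1, "", "GLY"), Atom(f"F{i}", "C", c))
        for i, c in enumerate(rep_xyz):
            topo.add_atom(ResidueKey("R", 2, "", "GLY"), Atom(f"P{i}", "C", c))
        frames = []
        for t in range(10):
            frames.append(np.vstack([fit_xyz, rep_xyz + [0.0, 0.0, 0.2 * t]]))
        traj = Trajectory(topo, frames)
        series = rmsd_series(traj, np.arange(6), np.arange(6, 10))
        expected = [0.2 * t for t in range(10)]
        assert np.abs(series.values - expected).max() < 1e-9


class TestMinDistanceSeries:
    def test_constant_pair_plateaus(self):
        """A pair fixed 7 A apart reads as a flat 7.0 A series."""
        topo = Structure()
        topo.add_atom(ResidueKey("R", 1, "", "GLY"), Atom("CA", "C", [0.0, 0.0, 0.0]))
        topo.add_atom(ResidueKey("R", 2, "", "GLY"), Atom("CA", "C", [7.0, 0.0, 0.0]))
        traj = Trajectory(topo, [topo.coords() for _ in range(10)])
        series = min_distance_series(traj, "R", 1, "R", 2)
        assert len(series) == 10
        assert np.abs(series.values - 7.0).max() < 1e-12

    def test_separating_pair_strictly_increases(self):
        topo = Structure()
        topo.add_atom(ResidueKey("R", 1, "", "GLY"), Atom("CA", "C", [0.0, 0.0, 0.0]))
        topo.add_atom(ResidueKey("R", 2, "", "GLY"), Atom("CA", "C", [3.0, 0.0, 0.0]))
        frames = [np.array([[0.0, 0.0, 0.0], [3.0 + 0.5 * t, 0.0, 0.0]]) for t in range(6)]
        series = min_distance_series(Trajectory(topo, frames), "R", 1, "R", 2)
        assert np.all(np.diff(series.values) > 0)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_random_walk_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        topo = Structure()
        for i in range(4):
            topo.add_atom(ResidueKey("R", 1, "", "GLY"), Atom(f"A{i}", "C", np.zeros(3)))
        for i in range(5):
            topo.add_atom(ResidueKey("R", 2, "", "GLY"), Atom(f"B{i}", "C", np.zeros(3)))
        frames = [rng.uniform(0, 10, size=(9, 3)) for _ in range(12)]
        traj = Trajectory(topo, frames)
        series = min_distance_series(traj, "R", 1, "R", 2)
        for t, frame in enumerate(frames):
            oracle = min(
                np.linalg.norm(a - b) for a in frame[:4] for b in frame[4:]
            )
            assert series.values[t] == pytest.approx(oracle, abs=1e-12)


class TestHBondProbability:
    def test_planted_seven_of_ten(self):
        traj, ledger = synthetic.make_hbond_traj(0.7, 10, seed=1)
        assert hbond_probability(traj, ("R", 1), ("R", 2)) == ledger["occupancy"] == 0.7

    def test_never_bonded(self):
        traj, _ = synthetic.make_hbond_traj(0.0, 10, seed=1)
        assert hbond_probability(traj, ("R", 1), ("R", 2)) == 0.0

    @pytest.mark.parametrize("p", [0.0, 0.3, 0.5, 0.9, 1.0])
    @pytest.mark.parametrize("T", [7, 10, 16])
    def test_exact_over_occupancy_grid(self, p, T):
        traj, _ = synthetic.make_hbond_traj(p, T, seed=5)
        assert hbond_probability(traj, ("R", 1), ("R", 2)) == round(p * T) / T

    def test_monotone_in_distance_cutoff(self):
        traj, _ = synthetic.make_hbond_traj(0.4, 10, seed=2)
        probs = [
            hbond_probability(traj, ("R", 1), ("R", 2), HBondCriterion(donor_acceptor_cutoff=c))
            for c in (2.0, 2.8, 3.5, 8.5)
        ]
        assert probs == sorted(probs)
        assert all(0.0 <= p <= 1.0 for p in probs)

    def test_angle_criterion_with_hydrogens(self):
        """With explicit hydrogens, a straight D-H...A geometry passes and a
        bent one (H-D-A angle > 30 deg) fails."""
        def traj_with_h(h_pos):
            topo = Structure()
            don = ResidueKey("R", 1, "", "SER")
            acc = ResidueKey("R", 2, "", "ASP")
            topo.add_atom(don, Atom("OG", "O", [0.0, 0.0, 0.0]))
            topo.add_atom(don, Atom("HG", "H", h_pos, is_hydrogen=True))
            topo.add_atom(acc, Atom("OD1", "O", [3.0, 0.0, 0.0]))
            return Trajectory(topo, [topo.coords()])

        straight = traj_with_h([1.0, 0.0, 0.0])
        bent = traj_with_h([0.0, 1.0, 0.0])  # 90 deg H-D-A
        crit = HBondCriterion(require_hydrogens=True)
        assert hbond_probability(straight, ("R", 1), ("R", 2), crit) == 1.0
        assert hbond_probability(bent, ("R", 1), ("R", 2), crit) == 0.0

    def test_missing_donors_rejected(self):
        traj, _ = synthetic.make_hbond_traj(0.5, 4, seed=0)
        with pytest.raises(ValueError, match="acceptor"):
            hbond_probability(traj, ("R", 1), ("R", 1))


class TestWaterDensityGrid:
    def test_single_stationary_water_analytic_value(self):
        """A water exactly on a grid point contributes 1/V_r = 3/(4 pi)."""
        traj = water_box_traj([[[1.0, 1.0, 1.0]]] * 5)
        grid = water_density_grid(
            traj, GridRegion([0.0, 0.0, 0.0], [2.0, 2.0, 2.0]), spacing=0.5, r=1.0
        )
        centre = grid.values[2, 2, 2]
        assert centre == pytest.approx(3.0 / (4.0 * math.pi), rel=1e-12)
        assert grid.values[0, 0, 0] == 0.0  # farther than 1 A

    def test_bit_equal_to_heaviside_double_sum(self):
        rng = np.random.default_rng(9)
        frames = [rng.uniform(0, 3, size=(3, 3)) for _ in range(2)]
        traj = water_box_traj(frames)
        region = GridRegion([0.0, 0.0, 0.0], [1.2, 1.2, 1.2])
        grid = water_density_grid(traj, region, spacing=0.4, r=1.0)
        oracle = brute_force_density(frames, grid.point_coords(), r=1.0)
        assert np.array_equal(grid.values.reshape(-1), oracle)

    def test_unbiased_on_uniform_hydration(self):
        traj, ledger = synthetic.make_hydration_traj(
            synthetic.HydrationSpec(box=12.0, density=0.0334, frames=50, seed=11)
        )
        fit = select_atoms(traj.topology, chain="R")
        region = GridRegion([2.0, 2.0, 2.0], [10.0, 10.0, 10.0])
        grid = water_density_grid(traj, region, spacing=0.4, r=1.0, fit_indices=fit)
        assert grid.values.mean() == pytest.approx(ledger["density"], rel=0.05)

    def test_superposition_invariance(self):
        """Rigidly transforming all frames leaves the receptor-frame grid
        unchanged, because frames are superposed on frame 0 first."""
        traj, _ = synthetic.make_hydration_traj(
            synthetic.HydrationSpec(box=8.0, density=0.02, frames=5, seed=3)
        )
        fit = select_atoms(traj.topology, chain="R")
        region = GridRegion([1.0, 1.0, 1.0], [7.0, 7.0, 7.0])
        base = water_density_grid(traj, region, spacing=0.8, r=1.0, fit_indices=fit)
        rng = np.random.default_rng(4)
        moved_frames = [traj.frames[0]]
        for frame in traj.frames[1:]:
            rot, trans = random_rigid_transform(rng)
            moved_frames.append(frame @ rot.T + trans)
        moved = Trajectory(traj.topology, moved_frames)
        grid2 = water_density_grid(moved, region, spacing=0.8, r=1.0, fit_indices=fit)
        assert np.abs(grid2.values - base.values).max() < 1e-9

    def test_zero_waters_warns_and_returns_zero_grid(self):
        topo = Structure()
        topo.add_atom(ResidueKey("R", 1, "", "GLY"), Atom("CA", "C", np.zeros(3)))
        traj = Trajectory(topo, [topo.coords()])
        with pytest.warns(UserWarning, match="no water"):
            grid = water_density_grid(traj, GridRegion([0, 0, 0], [2, 2, 2]), spacing=1.0)
        assert np.all(grid.values == 0.0)

    def test_invalid_parameters_rejected(self):
        traj = water_box_traj([[[0.0, 0.0, 0.0]]])
        region = GridRegion([0, 0, 0], [2, 2, 2])
        with pytest.raises(ValueError):
            water_density_grid(traj, region, spacing=-0.4)
        with pytest.raises(ValueError):
            water_density_grid(traj, region, r=0.0)


class TestHighDensityRegions:
    def make_grid(self, values):
        from gpcrprofile.structio import DensityGrid

        return DensityGrid(
            origin=np.zeros(3), spacing=0.4, values=values, bulk_density=BULK_WATER_DENSITY
        )

    def test_planted_block_found_with_peak_ratio(self):
        values = np.full((9, 9, 9), BULK_WATER_DENSITY)
        values[3:6, 3:6, 3:6] = 2.5 * BULK_WATER_DENSITY
        clusters = high_density_regions(self.make_grid(values), k=2.0)
        assert len(clusters) == 1
        assert clusters[0].peak_ratio == pytest.approx(2.5)
        assert clusters[0].size == 27

    def test_uniform_bulk_has_no_clusters(self):
        values = np.full((6, 6, 6), BULK_WATER_DENSITY)
        assert high_density_regions(self.make_grid(values), k=2.0) == []

    def test_two_separated_blocks_give_two_clusters(self):
        values = np.full((12, 6, 6), BULK_WATER_DENSITY)
        values[1:3, 1:3, 1:3] = 3.0 * BULK_WATER_DENSITY
        values[8:11, 2:4, 2:4] = 2.2 * BULK_WATER_DENSITY
        clusters = high_density_regions(self.make_grid(values), k=2.0)
        assert len(clusters) == 2
        assert clusters[0].peak_ratio == pytest.approx(3.0)  # sorted by peak
        assert clusters[0].size == 8 and clusters[1].size == 12

    def test_hotspot_trajectory_detected(self):
        spec = synthetic.HydrationSpec(
            box=12.0, density=0.0334, frames=200, seed=2,
            hotspot_center=np.array([6.0, 6.0, 6.0]), hotspot_radius=2.0,
            hotspot_multiplier=2.5,
        )
        traj, ledger = synthetic.make_hydration_traj(spec)
        fit = select_atoms(traj.topology, chain="R")
        region = GridRegion([2.0, 2.0, 2.0], [10.0, 10.0, 10.0])
        grid = water_density_grid(traj, region, spacing=0.4, r=1.0, fit_indices=fit)
        clusters = high_density_regions(grid, k=2.0)
        assert len(clusters) == 1
        peak_xyz = grid.origin + np.array(clusters[0].peak_index) * 0.4
        assert np.linalg.norm(peak_xyz - spec.hotspot_center) < spec.hotspot_radius

    def test_missing_bulk_density_rejected(self):
        from gpcrprofile.structio import DensityGrid

        grid = DensityGrid(origin=np.zeros(3), spacing=0.4, values=np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="bulk"):
            high_density_regions(grid, k=2.0)
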