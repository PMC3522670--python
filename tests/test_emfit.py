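import numpy as np
import pytest

from emassemble.densmap import DensityGrid, GaussianParams, simulate_map
from emassemble.emfit import (EmFitWeights, MaxOverlapTable, accumulate_voxel_density,
                              build_assembly_table, calibrate_max_overlap,
                              density_clash_energy, em_fit_energy, gaussian_overlap,
                              interpolate_overlap, pair_overlap_gradient,
                              precompute_overlap_grid)
from emassemble.structures import Assembly, CoarseModel, RigidPose
from conftest import fd_force_check


def single_voxel_grid(value=1.0, n=9, voxel=10.0):
    v = np.zeros((n, n, n))
    v[n // 2, n // 2, n // 2] = value
    return DensityGrid(np.full(3, -(n // 2) * voxel), voxel, v)


class TestGaussianOverlap:
    def test_matches_numeric_integration(self):
        """Closed form against a brute-force Riemann sum of the 3D product."""
        g1 = GaussianParams(sigma=5.0, amplitude=1.0)
        g2 = GaussianParams(sigma=5.0, amplitude=1.0)
        D = 3.0
        O, _ = gaussian_overlap(D, g1, g2)
        ax = np.linspace(-30, 30, 121)
        dx = ax[1] - ax[0]
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        f = (np.exp(-g1.s * (X**2 + Y**2 + Z**2))
             * np.exp(-g2.s * ((X - D) ** 2 + Y**2 + Z**2)))
        riemann = f.sum() * dx**3
        assert O == pytest.approx(riemann, rel=1e-4)

    def test_monotone_decreasing_and_symmetric(self):
        g1 = GaussianParams(4.0, 2.0)
        g2 = GaussianParams(7.0, 0.5)
        D = np.linspace(0.0, 30.0, 50)
        O, _ = gaussian_overlap(D, g1, g2)
        assert np.all(np.diff(O) < 0)
        O_swapped, _ = gaussian_overlap(D, g2, g1)
        np.testing.assert_allclose(O, O_swapped, rtol=1e-14)

    def test_derivative_matches_fd(self):
        g = GaussianParams(5.0)
        D = 4.0
        h = 1e-6
        O, dO = gaussian_overlap(D, g, g)
        fd = (gaussian_overlap(D + h, g, g)[0] - gaussian_overlap(D - h, g, g)[0]) / (2 * h)
        assert dO == pytest.approx(fd, rel=1e-6)

    def test_cartesian_gradient(self):
        g = GaussianParams(5.0)
        delta = np.array([3.0, -1.0, 2.0])
        O, grad = pair_overlap_gradient(delta, g, g)
        gamma = g.s * g.s / (2 * g.s)
        np.testing.assert_allclose(grad, -2 * gamma * delta * O, rtol=1e-12)


class TestPrecompute:
    def test_single_voxel_map_equals_closed_form(self):
        grid = single_voxel_grid(value=2.0)
        atom = GaussianParams.from_resolution(40.0)
        og = precompute_overlap_grid(grid, atom)
        vox = GaussianParams(atom.sigma, 1.0)
        ii = np.arange(9) - 4
        for idx in [(4, 4, 4), (0, 0, 0), (2, 6, 3)]:
            D = 10.0 * np.linalg.norm(np.array(idx) - 4)
            expected = 2.0 * gaussian_overlap(D, atom, vox)[0]
            assert og.values[idx] == pytest.approx(expected, rel=1e-6)

    def test_zero_map_and_linearity(self):
        atom = GaussianParams.from_resolution(40.0)
        zero = DensityGrid(np.zeros(3), 10.0, np.zeros((5, 5, 5)))
        og0 = precompute_overlap_grid(zero, atom)
        assert np.allclose(og0.values, 0.0)
        g = single_voxel_grid()
        o1 = precompute_overlap_grid(g, atom)
        g2 = DensityGrid(g.origin, g.voxel_size, 2 * g.values)
        o2 = precompute_overlap_grid(g2, atom)
        np.testing.assert_allclose(o2.values, 2 * o1.values, rtol=1e-10)

    def test_gradient_field_consistent_with_value_differences(self, toy_ring):
        assembly, _ = toy_ring
        m = simulate_map(assembly, 40.0, voxel_size=10.0)
        og = precompute_overlap_grid(m, GaussianParams.from_resolution(40.0))
        # central differences of O vs stored analytic gradient, interior voxels
        h = m.voxel_size
        num = (og.values[2:, 1:-1, 1:-1] - og.values[:-2, 1:-1, 1:-1]) / (2 * h)
        ana = og.gradient[1:-1, 1:-1, 1:-1, 0]
        mask = np.abs(num) > 0.05 * np.abs(num).max()
        rel = np.abs(ana[mask] - num[mask]) / np.abs(num[mask])
        assert np.median(rel) < 0.05


class TestInterpolation:
    def test_voxel_center_exact_and_weights(self, toy_map40):
        og = precompute_overlap_grid(toy_map40, GaussianParams.from_resolution(40.0))
        idx = (3, 4, 2)
        pos = toy_map40.grid_to_world(idx)
        O, G, w, outside = interpolate_overlap(og, pos)
        assert not outside
        assert O == pytest.approx(og.values[idx], rel=1e-12)
        assert w.max() == pytest.approx(1.0) and w.sum() == pytest.approx(1.0)

    def test_trilinear_midpoint_is_mean(self, toy_map40):
        og = precompute_overlap_grid(toy_map40, GaussianParams.from_resolution(40.0))
        a, b = (3, 4, 2), (4, 4, 2)
        mid = 0.5 * (toy_map40.grid_to_world(a) + toy_map40.grid_to_world(b))
        O, _, w, _ = interpolate_overlap(og, mid, method="trilinear")
        assert O == pytest.approx(0.5 * (og.values[a] + og.values[b]), rel=1e-12)
        np.testing.assert_allclose(sorted(w)[-2:], [0.5, 0.5], atol=1e-12)

    def test_matches_direct_summation_oracle(self, toy_ring):
        """Interpolated overlap vs full direct Gaussian summation, random
        positions in the fitting region of a 40 A map."""
        assembly, _ = toy_ring
        m = simulate_map(assembly, 40.0, voxel_size=10.0)
        atom = GaussianParams.from_resolution(40.0)
        og = precompute_overlap_grid(m, atom)
        vox = GaussianParams(atom.sigma, 1.0)
        centers = np.stack(np.meshgrid(
            *[m.origin[a] + m.voxel_size * np.arange(m.dims[a]) for a in range(3)],
            indexing="ij"), axis=-1).reshape(-1, 3)
        rho = m.values.ravel()
        rng = np.random.default_rng(0)
        beads = assembly.coordinates()
        pts = beads[rng.choice(len(beads), 100)] + rng.normal(scale=3.0, size=(100, 3))
        O_i, _, _, _ = interpolate_overlap(og, pts)
        for p, o in zip(pts, O_i):
            D = np.linalg.norm(centers - p, axis=1)
            direct = (rho * gaussian_overlap(D, atom, vox)[0]).sum()
            assert abs(o - direct) / direct < 1e-3

    def test_outside_positions_flagged(self, toy_map40):
        og = precompute_overlap_grid(toy_map40, GaussianParams.from_resolution(40.0))
        far = toy_map40.origin - 50.0
        _, _, _, outside = interpolate_overlap(og, far)
        assert outside


class TestCalibration:
    def test_single_bead_self_overlap(self):
        bead = CoarseModel(np.array([[0.0, 0, 0]]), np.array([1.0]),
                           np.array(["BB"]), np.array([1]))
        table, _ = calibrate_max_overlap(bead, 40.0, voxel_size=10.0, padding=60.0)
        atom = GaussianParams.from_resolution(40.0)
        # analytic: the bead's own map voxel-sampled Gaussian against a probe
        # equals the two-Gaussian overlap at D=0 times the map amplitude sum
        # -> compare against the direct-summation value instead of pair form
        m = simulate_map(bead, 40.0, voxel_size=10.0, padding=60.0)
        centers = np.stack(np.meshgrid(
            *[m.origin[a] + 10.0 * np.arange(m.dims[a]) for a in range(3)],
            indexing="ij"), axis=-1).reshape(-1, 3)
        D = np.linalg.norm(centers, axis=1)
        vox = GaussianParams(atom.sigma, 1.0)
        direct = (m.values.ravel() * gaussian_overlap(D, atom, vox)[0]).sum()
        assert table.per_component[0][0] == pytest.approx(direct, rel=1e-3)

    def test_core_bead_exceeds_isolated_bead(self, toy_ring):
        """Spillover: a bead in a compact cluster calibrates higher than an
        isolated distant bead of equal weight."""
        positions = np.vstack([np.random.default_rng(0).normal(scale=3, size=(10, 3)),
                               [[60.0, 0.0, 0.0]]])
        w = np.ones(11)
        model = CoarseModel(positions, w, np.array(["BB"] * 11), np.arange(11))
        table, _ = calibrate_max_overlap(model, 40.0, voxel_size=10.0)
        vals = table.per_component[0]
        assert vals[:10].min() > vals[10]

    def test_deterministic(self, toy_ring):
        _, sub = toy_ring
        t1, _ = calibrate_max_overlap(sub, 40.0, voxel_size=10.0)
        t2, _ = calibrate_max_overlap(sub, 40.0, voxel_size=10.0)
        np.testing.assert_array_equal(t1.per_component[0], t2.per_component[0])

    def test_table_invariants(self):
        with pytest.raises(ValueError):
            MaxOverlapTable(per_component=[np.array([1.0])], F=0.5)
        with pytest.raises(ValueError):
            MaxOverlapTable(per_component=[np.array([-1.0])], F=2.0)


class TestEmFitEnergy:
    @pytest.fixture()
    def setup(self, toy_ring, toy_map40):
        assembly, sub = toy_ring
        atom = GaussianParams.from_resolution(40.0)
        og = precompute_overlap_grid(toy_map40, atom)
        tab, _ = calibrate_max_overlap(sub, 40.0, voxel_size=toy_map40.voxel_size)
        return assembly, og, tab

    def test_zero_energy_at_calibration_pose(self, setup):
        """A single component at its own calibration pose with F=1 meets its
        maximum overlap exactly (here: overlap can only exceed it thanks to
        neighbour spillover)."""
        assembly, og, tab = setup
        T = build_assembly_table([tab] * assembly.n_components, F=1.0)
        e, _ = em_fit_energy(assembly, og, T)
        assert e == pytest.approx(0.0, abs=1e-9)

    def test_calibration_pose_is_minimum_under_rigid_displacement(self, toy_ring, rng):
        """On its own noise-free self-map with F=1, a component's calibration
        pose scores (near) zero and every >=5 A rigid displacement scores
        higher."""
        _, sub = toy_ring
        tab, og_self = calibrate_max_overlap(sub, 40.0, voxel_size=10.0)
        single = Assembly([sub])
        T = build_assembly_table([tab], F=1.0)
        e0, _ = em_fit_energy(single, og_self, T)
        assert e0 == pytest.approx(0.0, abs=1e-9)
        from emassemble.synthetic import perturb_assembly
        for _ in range(50):
            pert = perturb_assembly(single, 5.0 + 5.0 * rng.random(), 0.3, rng)
            e, _ = em_fit_energy(pert, og_self, T)
            assert e > e0

    def test_forces_match_finite_differences(self, setup, rng):
        assembly, og, tab = setup
        T = build_assembly_table([tab] * assembly.n_components, F=2.0)
        from emassemble.synthetic import perturb_assembly
        pert = perturb_assembly(assembly, 4.0, 0.2, rng)
        coords = pert.coordinates()
        _, forces = em_fit_energy(pert, og, T, coords=coords)
        fd_force_check(lambda c: em_fit_energy(pert, og, T, coords=c)[0],
                       coords, forces, rng)

    def test_f_below_one_rejected(self, setup):
        _, _, tab = setup
        with pytest.raises(ValueError):
            build_assembly_table([tab], F=0.9)


class TestVoxelDensity:
    def test_bead_at_voxel_center(self, toy_map40):
        pos = toy_map40.grid_to_world((3, 3, 3))
        vd = accumulate_voxel_density(pos[None, :], np.array([1.0]), toy_map40)
        assert vd.grid.values[3, 3, 3] == pytest.approx(1.0)
        assert vd.grid.values.sum() == pytest.approx(1.0)

    def test_bead_at_cell_corner_splits_equally(self, toy_map40):
        corner = toy_map40.grid_to_world((3, 3, 3)) + toy_map40.voxel_size / 2.0
        vd = accumulate_voxel_density(corner[None, :], np.array([1.0]), toy_map40)
        nz = vd.grid.values[vd.grid.values > 0]
        assert len(nz) == 8
        np.testing.assert_allclose(nz, 0.125, rtol=1e-9)

    def test_total_weight_conserved(self, toy_ring, toy_map40, rng):
        assembly, _ = toy_ring
        vd = accumulate_voxel_density(assembly.coordinates(), assembly.weights(),
                                      toy_map40)
        assert vd.n_outside == 0
        assert vd.grid.values.sum() == pytest.approx(assembly.total_weight,
                                                     rel=1e-9)


class TestClashEnergy:
    def test_below_cap_no_energy(self, toy_ring, toy_map40):
        assembly, _ = toy_ring
        coords = assembly.coordinates()
        e, f, _ = density_clash_energy(coords, assembly.weights(), toy_map40,
                                       cap=1e9)
        assert e == 0.0 and np.all(f == 0.0)

    def test_colocated_beads_penalized_and_separation_helps(self, toy_map40):
        w = np.array([10.0, 10.0])
        center = toy_map40.grid_to_world((4, 4, 4))
        energies = []
        for sep in [0.0, 4.0, 8.0, 14.0, 22.0]:
            pts = np.array([center, center + [sep, 0, 0]])
            e, _, _ = density_clash_energy(pts, w, toy_map40, cap=12.0)
            energies.append(e)
        assert energies[0] > 0
        assert all(a >= b for a, b in zip(energies, energies[1:]))
        assert energies[-1] == 0.0

    def test_forces_match_finite_differences(self, toy_ring, toy_map40, rng):
        assembly, _ = toy_ring
        coords = assembly.coordinates()
        w = assembly.weights()
        cap = 0.4 * float(np.max(accumulate_voxel_density(
            coords, w, toy_map40).grid.values))
        e, forces, _ = density_clash_energy(coords, w, toy_map40, cap=cap)
        assert e > 0
        fd_force_check(lambda c: density_clash_energy(c, w, toy_map40, cap=cap)[0],
                       coords, forces, rng, h=1e-6)

    def test_invalid_cap(self, toy_map40):
        with pytest.raises(ValueError):
            density_clash_energy(np.zeros((1, 3)), np.ones(1), toy_map40, cap=0.0)
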