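"""Orientation reduction, depth weighting, activation maps, clusters."""

import numpy as np
import pytest

from freqtag.errors import ConfigError, DegenerateSourceError, InvalidGeometryError
from freqtag.grids import Leadfield, SourceGrid, cubic_grid, make_leadfield
from freqtag.source import (
    ActivationMap,
    FrequencyBin,
    depth_weights,
    neighbor_control_map,
    reduce_orientations,
    rms_activation,
    roi_extract,
    smooth_and_log,
    solve_l1_bin,
    voxelwise_cluster_test,
)


class TestReduceOrientations:
    def test_rank2_block_reproduced_exactly(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal((6, 2))
        v = rng.standard_normal((2, 3))
        block = u @ v  # exact rank 2
        grid = cubic_grid(1)
        lf = Leadfield(gain=block, grid=grid)
        rlf = reduce_orientations(lf)
        assert rlf.discarded_energy[0] == pytest.approx(0.0, abs=1e-25)
        # reduced columns reproduce the block on its own column space
        theta, phi = rlf.orientations[0]
        recon = np.outer(rlf.gain2[:, 0], theta) + np.outer(rlf.gain2[:, 1], phi)
        assert np.allclose(recon, block, atol=1e-12)

    def test_full_rank_reconstruction_error_is_third_singular_value(self):
        rng = np.random.default_rng(1)
        block = rng.standard_normal((8, 3))
        _, s, _ = np.linalg.svd(block)  # independent SVD oracle
        lf = Leadfield(gain=block, grid=cubic_grid(1))
        rlf = reduce_orientations(lf)
        theta, phi = rlf.orientations[0]
        recon = np.outer(rlf.gain2[:, 0], theta) + np.outer(rlf.gain2[:, 1], phi)
        assert np.linalg.norm(recon - block) == pytest.approx(s[2], rel=1e-9)
        assert rlf.discarded_energy[0] == pytest.approx(s[2] ** 2 / (s**2).sum())
        # orientation pair orthonormal
        assert abs(theta @ phi) < 1e-12
        assert np.linalg.norm(theta) == pytest.approx(1.0)

    def test_deterministic_under_repeats(self):
        lf = make_leadfield(5, 7, seed=2)
        a = reduce_orientations(lf)
        b = reduce_orientations(lf)
        assert np.array_equal(a.gain2, b.gain2)
        assert np.array_equal(a.orientations, b.orientations)

    def test_zero_block_raises(self):
        gain = np.zeros((4, 6))
        gain[:, 3:] = np.random.default_rng(3).standard_normal((4, 3))
        lf = Leadfield(gain=gain, grid=cubic_grid(2))
        with pytest.raises(DegenerateSourceError):
            reduce_orientations(lf)


class TestDepthWeights:
    def test_gamma_zero_uniform(self, small_leadfield):
        w = depth_weights(small_leadfield, gamma=0.0)
        assert np.allclose(w, 1.0)

    def test_arithmetic_two_sources(self):
        rng = np.random.default_rng(4)
        b1 = rng.standard_normal((5, 3))
        b1 /= np.linalg.norm(b1)
        b2 = rng.standard_normal((5, 3))
        b2 *= 4.0 / np.linalg.norm(b2)
        lf = Leadfield(gain=np.hstack([b1, b2]), grid=cubic_grid(2))
        w = depth_weights(lf, gamma=1.0)
        assert w == pytest.approx([0.4, 1.6])

    def test_depth_weighting_recovers_deep_source(self):
        """Weak deep source beats a high-gain superficial one only with
        depth weighting: gamma=1 localizes the deep source, gamma=0
        mislocalizes to the superficial neighbour."""
        m = 6
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.standard_normal((m, m)))
        d1, d2, d3, e2, e3 = q[:, 0], q[:, 1], q[:, 2], q[:, 3], q[:, 4]
        deep = np.column_stack([0.16 * d1, 0.10 * d2, 0.06 * d3])
        superficial = np.column_stack([5 * d1, 20 * e2, 3 * e3])
        lf = Leadfield(gain=np.hstack([deep, superficial]), grid=cubic_grid(2))
        kf = FrequencyBin(data=d1.astype(complex), freq=0.8)
        rlf = reduce_orientations(lf)
        picks = {}
        for gamma in (0.0, 1.0):
            sol = solve_l1_bin(kf, rlf.with_weights(depth_weights(lf, gamma)))
            amap = rms_activation(sol, lf.grid)
            picks[gamma] = int(np.argmax(amap.values))
        assert picks[0.0] == 1  # superficial wins without depth weighting
        assert picks[1.0] == 0  # deep source recovered with gamma = 1


class TestActivation:
    def test_zero_solution_zero_map(self, small_leadfield):
        rlf = reduce_orientations(small_leadfield)
        kf = FrequencyBin(data=np.zeros(12, dtype=complex), freq=0.8)
        sol = solve_l1_bin(kf, rlf)
        amap = rms_activation(sol, small_leadfield.grid)
        assert not amap.values.any()

    def test_single_component_arithmetic(self, small_leadfield):
        from freqtag.source import SourceSolution

        omega = np.zeros((27, 2), dtype=complex)
        omega[3, 0] = 2.0  # one real component = 2
        sol = SourceSolution(
            omega=omega, freq=0.8, objective=2.0, residual_norm=0.0,
            weights=np.ones(27),
        )
        amap = rms_activation(sol, small_leadfield.grid)
        assert amap.values[3] == pytest.approx(1.0)  # sqrt(4/4)
        assert not np.delete(amap.values, 3).any()

    def test_global_phase_invariance(self, small_leadfield):
        rng = np.random.default_rng(6)
        rlf = reduce_orientations(small_leadfield)
        x = np.zeros(27 * 4)
        x[4 * 5 : 4 * 5 + 4] = rng.standard_normal(4)
        from freqtag.source import _constraint_matrix

        A = _constraint_matrix(rlf)
        b = A @ x
        kf0 = (b[:12] + 1j * b[12:]).astype(complex)
        maps = []
        for alpha in np.linspace(0, 2 * np.pi, 7):
            kf = FrequencyBin(data=kf0 * np.exp(1j * alpha), freq=0.8)
            sol = solve_l1_bin(kf, rlf, tol=1e-10)
            maps.append(rms_activation(sol, small_leadfield.grid).values)
        for v in maps[1:]:
            assert np.allclose(v, maps[0], atol=1e-6 * maps[0].max())

    def test_solution_scaling_covariance(self, small_leadfield):
        rng = np.random.default_rng(7)
        rlf = reduce_orientations(small_leadfield)
        kf = FrequencyBin(
            data=rng.standard_normal(12) + 1j * rng.standard_normal(12), freq=0.8
        )
        s1 = solve_l1_bin(kf, rlf, tol=1e-9)
        s2 = solve_l1_bin(FrequencyBin(data=3.0 * kf.data, freq=0.8), rlf, tol=1e-9)
        assert s2.objective == pytest.approx(3 * s1.objective, rel=1e-6)
        v1 = rms_activation(s1, small_leadfield.grid).values
        v2 = rms_activation(s2, small_leadfield.grid).values
        assert np.allclose(v2, 3 * v1, atol=1e-6 * v1.max())


class TestControlAndSmoothing:
    def _map(self, values, grid):
        return ActivationMap(values=values, grid=grid, freq=0.8)

    def test_identical_neighbours(self):
        grid = cubic_grid(8)
        v = np.random.default_rng(8).uniform(size=8)
        c = neighbor_control_map(self._map(v, grid), self._map(v, grid))
        assert np.allclose(c.values, v)

    def test_per_voxel_mean(self):
        grid = cubic_grid(4)
        c = neighbor_control_map(
            self._map(np.zeros(4), grid), self._map(np.full(4, 2.0), grid)
        )
        assert np.allclose(c.values, 1.0)

    def test_grid_mismatch(self):
        a = self._map(np.ones(8), cubic_grid(8))
        b = self._map(np.ones(27), cubic_grid(27))
        with pytest.raises(InvalidGeometryError):
            neighbor_control_map(a, b)

    def test_control_variance_halves(self):
        rng = np.random.default_rng(9)
        grid = cubic_grid(64)
        var_single, var_control = [], []
        for _ in range(200):
            a, b = rng.uniform(size=(2, 64))
            c = neighbor_control_map(self._map(a, grid), self._map(b, grid))
            var_single.append(a.var())
            var_control.append(c.values.var())
        assert np.mean(var_control) / np.mean(var_single) == pytest.approx(0.5, rel=0.1)

    def test_fwhm_zero_identity_and_uniform_fixed_point(self):
        grid = cubic_grid(27)
        v = np.random.default_rng(10).uniform(1, 2, 27)
        out = smooth_and_log(self._map(v, grid), fwhm=0.0, log=False)
        assert np.allclose(out.values, v)
        # log of uniform is uniform (no smoothing)
        u0 = smooth_and_log(self._map(np.full(27, 3.0), grid), fwhm=0.0, log=True)
        assert np.allclose(u0.values, np.log(3.0))
        # smoothing a uniform map: mass conserved exactly, interior
        # voxel unchanged up to boundary normalization
        grid5 = cubic_grid(125)
        u = smooth_and_log(self._map(np.full(125, 3.0), grid5), fwhm=5.0, log=False)
        assert u.values.sum() == pytest.approx(125 * 3.0, rel=1e-12)
        assert u.values[62] == pytest.approx(3.0, rel=0.01)

    def test_delta_mass_conserved_interior(self):
        grid = cubic_grid(125)  # 5x5x5, interior voxel has full neighbourhood
        centre = 62
        delta = np.zeros(125)
        delta[centre] = 1.0
        sm = smooth_and_log(self._map(delta, grid), fwhm=10.0, log=False)
        assert sm.values.sum() == pytest.approx(1.0, rel=0.01)

    def test_all_zero_map_warns_and_floors(self):
        grid = cubic_grid(8)
        with pytest.warns(UserWarning, match="log-floored"):
            out = smooth_and_log(self._map(np.zeros(8), grid), fwhm=0.0)
        assert np.all(np.isfinite(out.values))


class TestClusterTest:
    def test_no_effect_no_clusters(self):
        grid = cubic_grid(27)
        maps = np.random.default_rng(11).uniform(size=(8, 27))
        res = voxelwise_cluster_test(maps, maps.copy(), grid)
        assert res.clusters == []

    def test_injected_effect_recovered(self):
        rng = np.random.default_rng(12)
        grid = cubic_grid(64)
        centre = 21
        nb = grid.adjacency()[centre]
        region = np.concatenate([[centre], nb[:6]])
        target = rng.standard_normal((12, 64)) * 0.5
        control = rng.standard_normal((12, 64)) * 0.5
        target[:, region] += 1.2  # strong paired effect in one region
        res = voxelwise_cluster_test(target, control, grid, seed=0)
        assert len(res.significant) >= 1
        best = max(res.significant, key=lambda c: c["peak_t"])
        d = np.linalg.norm(
            grid.positions[best["peak"]] - grid.positions[centre]
        )
        assert d <= grid.spacing * np.sqrt(3) + 1e-9

    def test_exhaustive_enumeration_small_n(self):
        rng = np.random.default_rng(13)
        grid = cubic_grid(8)
        target = rng.standard_normal((5, 8)) + 3.0
        control = rng.standard_normal((5, 8))
        res = voxelwise_cluster_test(target, control, grid, n_permutations=1024)
        # 2^5 = 32 sign patterns enumerated: p values are multiples of 1/33
        for c in res.clusters:
            assert c["p"] >= 1 / 33 - 1e-12

    def test_requires_three_subjects(self):
        grid = cubic_grid(8)
        with pytest.raises(ConfigError):
            voxelwise_cluster_test(np.ones((2, 8)), np.zeros((2, 8)), grid)


class TestRoi:
    def test_small_cube_returns_peak_value(self):
        grid = cubic_grid(27)
        v = np.arange(27.0)
        amap = ActivationMap(values=v, grid=grid)
        assert roi_extract(amap, peak=13, half_size=2.0) == 13.0

    def test_uniform_map(self):
        amap = ActivationMap(values=np.full(27, 5.0), grid=cubic_grid(27))
        assert roi_extract(amap, peak=0, half_size=7.5) == 5.0

    def test_smoothed_delta_roi_larger_at_centre(self):
        grid = cubic_grid(125)
        delta = np.zeros(125)
        delta[62] = 1.0
        sm = smooth_and_log(ActivationMap(values=delta, grid=grid), fwhm=10.0, log=False)
        near = roi_extract(sm, peak=62, half_size=5.0)
        far = roi_extract(sm, peak=0, half_size=5.0)
        assert near > far
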