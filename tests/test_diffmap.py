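import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kinmap as km
from kinmap.diffmap import median_sq_distance, _align_to_reference


class TestGaussianKernel:
    def test_identical_points_and_unit_diagonal(self):
        pts = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        K = km.gaussian_kernel(pts, km.KernelSpec(epsilon=1.0))
        assert K[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(K), 1.0)

    def test_distance_sqrt_two_epsilon_gives_inverse_e(self):
        eps = 0.7
        pts = np.array([[0.0], [np.sqrt(2 * eps)]])
        K = km.gaussian_kernel(pts, km.KernelSpec(epsilon=eps))
        assert K[0, 1] == pytest.approx(np.exp(-1.0))

    def test_collinear_points_hand_evaluation(self):
        eps = 0.5
        pts = np.array([[0.0], [1.0], [2.0]])
        K = km.gaussian_kernel(pts, km.KernelSpec(epsilon=eps))
        expected = np.exp(-np.array([[0, 1, 4], [1, 0, 1], [4, 1, 0]]) / (2 * eps))
        assert np.allclose(K, expected, atol=1e-15)
        assert np.max(np.abs(K - K.T)) < 1e-15

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            km.gaussian_kernel(np.array([[0.0], [np.nan]]), km.KernelSpec(epsilon=1.0))


class TestBuildTransitionMatrix:
    def test_two_identical_points_half_half(self):
        K = np.ones((2, 2))
        for norm in ("row", "density_corrected"):
            M = km.build_transition_matrix(K, norm)
            assert np.allclose(M, 0.5)

    def test_uniform_kernel_gives_uniform_rows(self):
        K = np.full((5, 5), 0.3)
        M = km.build_transition_matrix(K, "row")
        assert np.allclose(M, 0.2)

    def test_row_normalization_entrywise(self):
        eps = 0.5
        pts = np.array([[0.0], [1.0], [2.0]])
        K = km.gaussian_kernel(pts, km.KernelSpec(epsilon=eps))
        M = km.build_transition_matrix(K, "row")
        assert np.allclose(M, K / K.sum(axis=1, keepdims=True))
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)


class TestDiffusionMap:
    def test_leading_eigenpair_is_trivial(self, circle200):
        res = km.diffusion_map(circle200, km.KernelSpec(), n_eigs=4)
        assert abs(res.eigenvalues[0] - 1.0) < 1e-10
        u1 = res.eigenvectors[:, 0]
        assert u1.std() / abs(u1.mean()) < 1e-8
        assert res.eigenvalues[0] > res.eigenvalues[1]

    def test_stationary_left_eigenvector(self, circle200):
        res = km.diffusion_map(circle200, km.KernelSpec(), n_eigs=3)
        assert res.stationary.min() >= 0
        assert res.stationary.sum() == pytest.approx(1.0)
        K = km.gaussian_kernel(circle200, km.KernelSpec(epsilon=res.epsilon))
        M = km.build_transition_matrix(K, "row")
        assert np.max(np.abs(res.stationary @ M - res.stationary)) < 1e-12

    def test_eigenpair_residuals_small(self, circle200):
        res = km.diffusion_map(circle200, km.KernelSpec(), n_eigs=4)
        K = km.gaussian_kernel(circle200, km.KernelSpec(epsilon=res.epsilon))
        M = km.build_transition_matrix(K, "row")
        for k in range(4):
            r = M @ res.eigenvectors[:, k] - res.eigenvalues[k] * res.eigenvectors[:, k]
            assert np.max(np.abs(r)) < 1e-8

    def test_two_separated_clusters_near_unit_second_eigenvalue(self):
        rng = np.random.default_rng(0)
        a = rng.normal(scale=0.05, size=(40, 2))
        b = rng.normal(scale=0.05, size=(40, 2)) + [3.0, 0.0]
        pts = np.vstack([a, b])
        # inter-cluster coupling ~ exp(-9/0.6) ~ 3e-7: metastable but connected
        res = km.diffusion_map(pts, km.KernelSpec(epsilon=0.3), n_eigs=3)
        assert res.eigenvalues[1] > 0.999
        u2 = res.eigenvectors[:, 1]
        assert np.all(np.sign(u2[:40]) == np.sign(u2[0]))
        assert np.all(np.sign(u2[40:]) == -np.sign(u2[0]))

    def test_circle_angle_recovery(self, circle200):
        res = km.diffusion_map(circle200, km.KernelSpec(), n_eigs=3)
        theta = 2 * np.pi * np.arange(200) / 200
        ang = np.arctan2(res.eigenvectors[:, 2], res.eigenvectors[:, 1])
        assert abs(km.circular_correlation(ang, theta)) > 0.99

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(60, 2))
        perm = rng.permutation(60)
        r1 = km.diffusion_map(pts, km.KernelSpec(epsilon=1.0), n_eigs=3)
        r2 = km.diffusion_map(pts[perm], km.KernelSpec(epsilon=1.0), n_eigs=3)
        assert np.max(np.abs(r1.eigenvalues - r2.eigenvalues)) < 1e-12
        for k in range(1, 3):
            a, b = r1.eigenvectors[perm, k], r2.eigenvectors[:, k]
            assert min(np.max(np.abs(a - b)), np.max(np.abs(a + b))) < 1e-8

    def test_all_eigenvalue_magnitudes_at_most_one(self, circle200):
        res = km.diffusion_map(circle200, km.KernelSpec(), n_eigs=6)
        assert np.all(np.abs(res.eigenvalues) <= 1 + 1e-12)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)  # descending

    def test_normalization_paths_qualitatively_similar(self):
        pts = km.sample_circle(150, noise_sd=0.05, seed=6).data
        eps = median_sq_distance(pts)
        r_row = km.diffusion_map(pts, km.KernelSpec(epsilon=eps), n_eigs=3)
        r_dc = km.diffusion_map(
            pts, km.KernelSpec(epsilon=eps, normalization="density_corrected"),
            n_eigs=3)
        assert np.allclose(r_row.eigenvalues[1:], r_dc.eigenvalues[1:], rtol=0.10)
        for k in (1, 2):
            r = np.corrcoef(r_row.eigenvectors[:, k], r_dc.eigenvectors[:, k])[0, 1]
            assert abs(r) > 0.9

    def test_cluster_gap_grows_with_separation(self):
        rng = np.random.default_rng(1)
        gaps = []
        for sep in (1.0, 2.0, 4.0):
            a = rng.normal(scale=0.2, size=(50, 2))
            b = rng.normal(scale=0.2, size=(50, 2)) + [sep, 0.0]
            res = km.diffusion_map(np.vstack([a, b]), km.KernelSpec(epsilon=0.5),
                                   n_eigs=3)
            gaps.append(res.eigenvalues[1] - res.eigenvalues[2])
        assert gaps[0] < gaps[1] < gaps[2]

    def test_disconnected_kernel_advises_larger_epsilon(self):
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [1e4, 0.0], [1e4, 0.1]])
        with pytest.raises(ValueError, match="epsilon"):
            km.diffusion_map(pts, km.KernelSpec(epsilon=0.01), n_eigs=2)


class TestSelectEpsilon:
    def test_two_points_median_is_squared_distance(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        eps, _ = km.select_epsilon(pts)
        assert eps == pytest.approx(25.0)

    def test_kernel_sum_saturates_at_n_and_n_squared(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(30, 2))
        med, _ = km.select_epsilon(pts)
        grid = med * np.logspace(-8, 8, 33)
        eps0, table = km.select_epsilon(pts, candidates=grid)
        assert table["kernel_sum"].iloc[0] == pytest.approx(30, rel=1e-6)
        assert table["kernel_sum"].iloc[-1] == pytest.approx(900, rel=1e-3)
        assert table["max_slope_region"].any()

    @settings(derandomize=True, max_examples=10)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_selected_epsilon_scales_with_squared_coordinates(self, c):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(40, 2))
        e1, _ = km.select_epsilon(pts)
        e2, _ = km.select_epsilon(pts * c)
        assert e2 == pytest.approx(e1 * c ** 2, rel=1e-9)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            km.select_epsilon(np.zeros((5, 2)))


class TestShortTimeDM:
    def test_window_identical_to_full_data_aligns_perfectly(self, circle200):
        spec = km.KernelSpec(epsilon=median_sq_distance(circle200))
        ref = km.diffusion_map(circle200, spec, n_eigs=3)
        wres = km.short_time_dm(circle200, spec, window_length=200, n_eigs=3,
                                reference=ref)
        assert wres.n_windows == 1
        assert sorted(wres.permutations[0].tolist()) == [0, 1]
        coords_ref = ref.dm_coordinates[:, 1:]
        coords_win = wres.aligned_coordinates(0)
        for k in range(2):
            r = np.corrcoef(coords_ref[:, k], coords_win[:, k])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_stationary_windows_track_full_trajectory_map(self):
        """Window eigenvectors of stationary single-well data correlate with
        the full-trajectory eigenvectors far above a shuffled-window null."""
        well = km.Well(np.array([0.0, 0.0]), depth=6.0, width=1.0)
        spec = km.LandscapeSpec(wells=(well,), n_frames=4000, stride_save=2,
                                seed=19)
        traj = km.simulate_brownian_2d(spec)
        kspec = km.KernelSpec(epsilon=median_sq_distance(traj.data[::10]))
        ref = km.diffusion_map(traj, kspec, n_eigs=3, stride=4)
        wres = km.short_time_dm(traj, kspec, window_length=400, n_eigs=3,
                                reference=ref)
        rs = []
        rng = np.random.default_rng(0)
        null = []
        for w in range(wres.n_windows):
            res = wres.results[w]
            common, ia, ib = np.intersect1d(res.sample_indices, ref.sample_indices,
                                            return_indices=True)
            u_win = res.eigenvectors[ia, 1]
            u_ref = ref.eigenvectors[ib, 1]
            rs.append(abs(np.corrcoef(u_win, u_ref)[0, 1]))
            null.append(abs(np.corrcoef(rng.permutation(u_win), u_ref)[0, 1]))
        assert np.mean(rs) > np.mean(null) + 0.3

    def test_transition_windows_fluctuate_more(self, brownian_threewell):
        from scipy.stats import mannwhitneyu
        _, traj, labels = brownian_threewell
        wl = 750
        eps = median_sq_distance(traj.data[::30])
        kspec = km.KernelSpec(epsilon=eps)
        ref = km.diffusion_map(traj, kspec, n_eigs=3, stride=30)
        wres = km.short_time_dm(traj, kspec, window_length=wl, n_eigs=3,
                                reference=ref)
        assert wres.n_windows >= 20
        lab = labels.labels
        has_trans = np.array([
            len(set(lab[w * wl:(w + 1) * wl][lab[w * wl:(w + 1) * wl] >= 0])) >= 2
            for w in range(wres.n_windows)])
        fl = wres.fluctuations.mean(axis=1)
        assert has_trans.any() and (~has_trans).any()
        _, p = mannwhitneyu(fl[has_trans], fl[~has_trans], alternative="greater")
        assert p < 0.05

    def test_previous_window_alignment_chains(self):
        rng = np.random.default_rng(23)
        pts = rng.normal(size=(300, 2))
        wres = km.short_time_dm(pts, km.KernelSpec(epsilon=2.0), window_length=100,
                                n_eigs=3, reference="previous")
        assert wres.n_windows == 3
        for w in range(3):
            assert sorted(wres.permutations[w].tolist()) == [0, 1]
            assert set(np.abs(wres.signs[w]).tolist()) == {1.0}

    def test_window_shorter_than_minimum_rejected(self):
        with pytest.raises(ValueError):
            km.short_time_dm(np.random.default_rng(0).normal(size=(50, 2)),
                             km.KernelSpec(epsilon=1.0), window_length=3, n_eigs=3)
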