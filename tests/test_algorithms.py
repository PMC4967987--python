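"""The five solvers: update rules vs. naive oracles, reductions, recovery."""

import numpy as np
import pytest

from fuzzyroi import (
    ClusterParams,
    ImageVolume,
    InitSpec,
    KernelSpec,
    NeighborhoodSpec,
    Nodule,
    ParameterError,
    PhantomSpec,
    generate_phantom,
    init_centroids,
    run_fcm,
    run_kfcm,
    run_mskfcm,
    run_sfcm,
    run_skfcm,
    select_nodule_cluster,
    tp_fp_rates,
)
from fuzzyroi.algorithms import (
    _Grid,
    fcm_centroids,
    fcm_memberships,
    kfcm_centroids,
    kfcm_memberships,
    skfcm_centroids,
    skfcm_memberships,
    spatial_function,
    spatial_memberships,
)
from conftest import random_memberships

import oracles

ATOL = 1e-9


def nbr_lists(shape, mask=None, size=3, mode="2d"):
    """Flat-index neighbor lists (center excluded) for the SKFCM oracle."""
    D, R, C = shape
    flat = {}
    pos = 0
    coords = []
    for z in range(D):
        for r in range(R):
            for c in range(C):
                if mask is None or mask[z][r][c]:
                    flat[(z, r, c)] = pos
                    coords.append((z, r, c))
                    pos += 1
    out = []
    for voxel in coords:
        nbrs = oracles.neighbors(shape, voxel, size, mode, include_center=False)
        out.append([flat[n] for n in nbrs if n in flat])
    return out


class TestInitCentroids:
    def test_operator_means(self, small_volume):
        init = InitSpec(mode="operator", samples=((-800.0, -820.0), (40.0,)))
        v = init_centroids(small_volume, ClusterParams(c=2), init)
        assert v.tolist() == [-810.0, 40.0]

    def test_operator_coordinates_looked_up(self, small_volume):
        init = InitSpec(mode="operator", samples=(((0, 0, 0),), ((0, 1, 1),)))
        v = init_centroids(small_volume, ClusterParams(c=2), init)
        assert v[0] == pytest.approx(small_volume.voxels[0, 0, 0])

    def test_operator_empty_sample_list_rejected(self, small_volume):
        with pytest.raises(ParameterError):
            init_centroids(
                small_volume, ClusterParams(c=2),
                InitSpec(mode="operator", samples=((1.0,), ())),
            )

    def test_random_reproducible_and_distinct(self, small_volume):
        init = InitSpec(mode="random", seed=42)
        v1 = init_centroids(small_volume, ClusterParams(c=4), init)
        v2 = init_centroids(small_volume, ClusterParams(c=4), init)
        assert np.array_equal(v1, v2)
        assert len(np.unique(v1)) == 4

    def test_constant_image_single_cluster(self):
        vol = ImageVolume(voxels=np.full((1, 3, 3), 50.0))
        v = init_centroids(vol, ClusterParams(c=1), InitSpec(mode="random", seed=0))
        assert v[0] == 50.0

    def test_constant_image_duplicates_perturbed(self):
        vol = ImageVolume(voxels=np.full((1, 3, 3), 50.0))
        v = init_centroids(vol, ClusterParams(c=3), InitSpec(mode="random", seed=0))
        assert len(np.unique(v)) == 3
        assert np.allclose(v, 50.0, atol=1e-10)


class TestMembershipUpdates:
    def test_fcm_hand_values(self):
        # x=1 between centroids 0 and 3, m=2: distances (1, 2) -> (0.8, 0.2)
        u = fcm_memberships(np.array([1.0]), np.array([0.0, 3.0]), 2.0)
        assert u[:, 0] == pytest.approx([0.8, 0.2], abs=ATOL)

    def test_fcm_equidistant_symmetry(self):
        u = fcm_memberships(np.array([5.0]), np.array([0.0, 10.0]), 2.0)
        assert u[:, 0] == pytest.approx([0.5, 0.5], abs=ATOL)

    def test_fcm_centroid_coincidence_is_crisp(self):
        u = fcm_memberships(np.array([3.0]), np.array([0.0, 3.0]), 2.0)
        assert u[:, 0] == pytest.approx([0.0, 1.0], abs=0)

    def test_kfcm_hand_value(self):
        # 1-K values (0.39347, 0.86466) at sigma=1, 2sigma^2 convention
        kern = KernelSpec(family="gaussian", sigma=1.0, variance_scale="2sigma2")
        u = kfcm_memberships(np.array([1.0]), np.array([0.0, 3.0]), 2.0, kern)
        # u0 = (1/0.393469) / (1/0.393469 + 1/0.864665)
        assert u[0, 0] == pytest.approx(0.68726, abs=5e-5)

    def test_kfcm_centroid_coincidence_is_crisp(self):
        kern = KernelSpec(family="gaussian", sigma=100.0)
        u = kfcm_memberships(np.array([-50.0]), np.array([-850.0, -50.0]), 2.0, kern)
        assert u[:, 0] == pytest.approx([0.0, 1.0], abs=0)

    @pytest.mark.parametrize("m", [1.5, 2.0, 3.0])
    def test_fcm_matches_oracle(self, rng, m):
        xs = rng.uniform(-1000, 100, 40)
        vs = rng.uniform(-1000, 100, 3)
        got = fcm_memberships(xs, vs, m)
        want = np.array(oracles.fcm_memberships(xs.tolist(), vs.tolist(), m))
        np.testing.assert_allclose(got, want, atol=ATOL, rtol=0)

    @pytest.mark.parametrize("m", [1.5, 2.0])
    def test_kfcm_matches_oracle(self, rng, m):
        xs = rng.uniform(-1000, 100, 40)
        vs = rng.uniform(-1000, 100, 3)
        kern = KernelSpec(family="gaussian", sigma=200.0)
        got = kfcm_memberships(xs, vs, m, kern)
        want = np.array(
            oracles.kfcm_memberships(xs.tolist(), vs.tolist(), m, sigma=200.0)
        )
        np.testing.assert_allclose(got, want, atol=ATOL, rtol=0)


class TestCentroidUpdates:
    def test_fcm_crisp_reduces_to_means(self):
        xs = np.array([0.0, 2.0, 10.0, 14.0])
        u = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
        v = fcm_centroids(xs, u, 2.0)
        assert v == pytest.approx([1.0, 12.0])

    def test_fcm_uniform_gives_global_mean(self):
        xs = np.array([0.0, 3.0, 9.0])
        u = np.full((3, 3), 1.0 / 3.0)
        v = fcm_centroids(xs, u, 2.0)
        assert v == pytest.approx([4.0, 4.0, 4.0])

    def test_fcm_hand_value(self):
        xs = np.array([0.0, 10.0])
        u = np.array([[0.8, 0.2], [0.2, 0.8]])
        v = fcm_centroids(xs, u, 2.0)
        assert v[0] == pytest.approx((0.64 * 0 + 0.04 * 10) / (0.64 + 0.04), abs=ATOL)

    def test_kfcm_single_voxel_fixed_point(self):
        kern = KernelSpec(family="gaussian", sigma=10.0)
        v = kfcm_centroids(np.array([7.0]), np.array([3.0]), np.array([[1.0]]), 2.0, kern)
        assert v[0] == pytest.approx(7.0)

    def test_kfcm_sigma_infinity_reduces_to_fcm(self, rng):
        xs = rng.uniform(-1000, 100, 30)
        u = random_memberships(rng, 3, 30)
        kern = KernelSpec(family="gaussian", sigma=1e12)
        got = kfcm_centroids(xs, rng.uniform(-500, 0, 3), u, 2.0, kern)
        want = fcm_centroids(xs, u, 2.0)
        np.testing.assert_allclose(got, want, atol=1e-6, rtol=0)

    def test_kfcm_matches_oracle(self, rng):
        xs = rng.uniform(-100, 100, 25)
        vs = rng.uniform(-100, 100, 2)
        u = random_memberships(rng, 2, 25)
        kern = KernelSpec(family="gaussian", sigma=5.0)
        got = kfcm_centroids(xs, vs, u, 2.0, kern)
        want = oracles.kfcm_centroids(xs.tolist(), vs.tolist(), u.tolist(), 2.0, sigma=5.0)
        np.testing.assert_allclose(got, want, atol=ATOL, rtol=0)

    def test_centroids_stay_in_data_range(self, rng):
        xs = rng.uniform(-1000, 100, 50)
        u = random_memberships(rng, 4, 50)
        for v in (
            fcm_centroids(xs, u, 2.0),
            kfcm_centroids(xs, rng.uniform(-500, 0, 4), u, 2.0, KernelSpec(sigma=300.0)),
        ):
            assert np.all(v >= xs.min() - 1e-12) and np.all(v <= xs.max() + 1e-12)


class TestSpatialMachinery:
    def test_uniform_memberships_interior_h(self):
        vol = ImageVolume(voxels=np.zeros((1, 5, 5)))
        c = 4
        u = np.full((c, 25), 1.0 / c)
        h = spatial_function(u, volume=vol, spec=NeighborhoodSpec(size=3))
        center = 2 * 5 + 2
        assert h[:, center] == pytest.approx([9.0 / c] * c)

    def test_crisp_window_counts(self):
        vol = ImageVolume(voxels=np.zeros((1, 3, 3)))
        u = np.zeros((2, 9))
        u[0] = 1.0
        h = spatial_function(u, volume=vol, spec=NeighborhoodSpec(size=3))
        assert h[0, 4] == 9.0 and h[1, 4] == 0.0

    @pytest.mark.parametrize("mode,include_center", [("2d", True), ("2d", False), ("3d", True)])
    def test_matches_double_loop_oracle(self, rng, mode, include_center):
        shape = (3, 5, 5) if mode == "3d" else (1, 5, 5)
        vol = ImageVolume(voxels=rng.uniform(-100, 100, shape))
        n = int(np.prod(shape))
        u = random_memberships(rng, 3, n)
        spec = NeighborhoodSpec(mode=mode, size=3, include_center=include_center)
        got = spatial_function(u, volume=vol, spec=spec)
        ug = u.reshape(3, *shape)
        want = np.array(
            oracles.spatial_function(ug.tolist(), 3, mode, include_center)
        ).reshape(3, n)
        np.testing.assert_allclose(got, want, atol=ATOL, rtol=0)

    def test_masked_neighbors_excluded(self, masked_volume, rng):
        n = int(masked_volume.mask_array().sum())
        u = random_memberships(rng, 2, n)
        spec = NeighborhoodSpec(size=3)
        got = spatial_function(u, volume=masked_volume, spec=spec)
        mask = masked_volume.mask_array()
        ug = np.zeros((2,) + mask.shape)
        ug.reshape(2, -1)[:, np.flatnonzero(mask.reshape(-1))] = u
        want_full = np.array(
            oracles.spatial_function(ug.tolist(), 3, "2d", True, mask=mask.tolist())
        )
        want = want_full.reshape(2, -1)[:, np.flatnonzero(mask.reshape(-1))]
        np.testing.assert_allclose(got, want, atol=ATOL, rtol=0)
        # column sums equal the in-window in-mask neighbor count
        grid = _Grid(masked_volume, spec)
        np.testing.assert_allclose(got.sum(axis=0), grid.n_r, atol=ATOL)

    def test_spatial_memberships_reductions_and_hand_value(self, rng):
        u = random_memberships(rng, 3, 10)
        h = rng.uniform(0.1, 5.0, (3, 10))
        np.testing.assert_allclose(spatial_memberships(u, h, 1.0, 0.0), u, atol=ATOL)
        np.testing.assert_allclose(
            spatial_memberships(u, h, 0.0, 1.0), h / h.sum(axis=0), atol=ATOL
        )
        up = spatial_memberships(
            np.array([[0.6], [0.4]]), np.array([[1.0], [3.0]]), 1.0, 1.0
        )
        assert up[:, 0] == pytest.approx([1.0 / 3.0, 2.0 / 3.0], abs=ATOL)

    def test_spatial_memberships_zero_normalizer_falls_back(self):
        u = np.array([[0.7], [0.3]])
        h = np.zeros((2, 1))
        up = spatial_memberships(u, h, 1.0, 1.0)
        np.testing.assert_allclose(up, u, atol=ATOL)

    def test_matches_oracle(self, rng):
        u = random_memberships(rng, 3, 20)
        h = rng.uniform(0.0, 9.0, (3, 20))
        got = spatial_memberships(u, h, 1.3, 0.7)
        want = np.array(oracles.spatial_memberships(u.tolist(), h.tolist(), 1.3, 0.7))
        np.testing.assert_allclose(got, want, atol=ATOL, rtol=0)


class TestSkfcmUpdates:
    def setup_method(self):
        self.kern = KernelSpec(family="gaussian", sigma=100.0, variance_scale="sigma2")

    def test_alpha_to_zero_equals_kfcm(self, small_volume, rng):
        xs = small_volume.masked_intensities()
        vs = np.array([-800.0, -100.0])
        grid = _Grid(small_volume, NeighborhoodSpec(size=3, include_center=False))
        tiny = 1e-12
        got = skfcm_memberships(xs, vs, 2.0, self.kern, grid, tiny)
        want = kfcm_memberships(xs, vs, 2.0, self.kern)
        np.testing.assert_allclose(got, want, atol=1e-9, rtol=0)
        u = random_memberships(rng, 2, xs.size)
        got_v = skfcm_centroids(xs, vs, u, 2.0, self.kern, grid, tiny)
        want_v = kfcm_centroids(xs, vs, u, 2.0, self.kern)
        np.testing.assert_allclose(got_v, want_v, atol=1e-9, rtol=0)

    def test_three_voxel_hand_computation(self):
        vol = ImageVolume(voxels=np.array([[[-800.0, -50.0, 40.0]]]))
        xs = vol.masked_intensities()
        vs = np.array([-800.0 + 1.0, 35.0])  # offset avoids the crisp singularity
        grid = _Grid(vol, NeighborhoodSpec(size=3, include_center=False))
        alpha = 0.1
        got = skfcm_memberships(xs, vs, 2.0, self.kern, grid, alpha)
        lists = nbr_lists((1, 1, 3))
        want = np.array(
            oracles.skfcm_memberships(
                xs.tolist(), vs.tolist(), 2.0, alpha, lists,
                sigma=100.0, variance_scale="sigma2",
            )
        )
        np.testing.assert_allclose(got, want, atol=ATOL, rtol=0)
        u = np.array([[0.9, 0.5, 0.1], [0.1, 0.5, 0.9]])
        got_v = skfcm_centroids(xs, vs, u, 2.0, self.kern, grid, alpha)
        want_v = oracles.skfcm_centroids(
            xs.tolist(), vs.tolist(), u.tolist(), 2.0, alpha, lists,
            sigma=100.0, variance_scale="sigma2",
        )
        np.testing.assert_allclose(got_v, want_v, atol=ATOL, rtol=0)

    def test_constant_image_centroid_is_constant(self):
        vol = ImageVolume(voxels=np.full((1, 4, 4), -120.0))
        xs = vol.masked_intensities()
        grid = _Grid(vol, NeighborhoodSpec(size=3, include_center=False))
        u = np.ones((1, 16))
        v = skfcm_centroids(xs, np.array([-120.0]), u, 2.0, self.kern, grid, 0.2)
        assert v[0] == pytest.approx(-120.0, abs=1e-12)

    def test_matches_oracle_on_random_image(self, rng):
        vol = ImageVolume(voxels=rng.uniform(-500, 100, (1, 6, 6)))
        xs = vol.masked_intensities()
        vs = rng.uniform(-500, 100, 3)
        grid = _Grid(vol, NeighborhoodSpec(size=3, include_center=False))
        lists = nbr_lists((1, 6, 6))
        got = skfcm_memberships(xs, vs, 2.0, self.kern, grid, 0.15)
        want = np.array(
            oracles.skfcm_memberships(
                xs.tolist(), vs.tolist(), 2.0, 0.15, lists,
                sigma=100.0, variance_scale="sigma2",
            )
        )
        np.testing.assert_allclose(got, want, atol=ATOL, rtol=0)

    def test_penalty_window_must_exclude_center(self, small_volume):
        with pytest.raises(ParameterError):
            from fuzzyroi.algorithms import _penalty_grid
            _penalty_grid(small_volume, NeighborhoodSpec(size=3, include_center=True))


TWO_POP = dict(mean_a=-850.0, mean_b=-50.0, sd=20.0, n=500)


def two_population_volume(seed=7):
    rng = np.random.default_rng(seed)
    x = np.concatenate([
        rng.normal(TWO_POP["mean_a"], TWO_POP["sd"], TWO_POP["n"]),
        rng.normal(TWO_POP["mean_b"], TWO_POP["sd"], TWO_POP["n"]),
    ])
    rng.shuffle(x)
    return ImageVolume(voxels=x.reshape(1, 20, 50))


OPERATOR2 = InitSpec(mode="operator", samples=((-850.0,), (-50.0,)))


class TestSolverRuns:
    @pytest.mark.parametrize("run", [run_fcm, run_kfcm, run_sfcm, run_skfcm, run_mskfcm])
    def test_constant_image_one_iteration(self, run):
        vol = ImageVolume(voxels=np.full((1, 4, 4), 77.0))
        st = run(vol, ClusterParams(c=1), InitSpec(mode="random", seed=0))
        assert st.iterations == 1 and st.converged
        assert st.centroids[0] == pytest.approx(77.0, abs=1e-9)

    def test_fcm_two_population_recovery(self):
        st = run_fcm(two_population_volume(), ClusterParams(c=2), OPERATOR2)
        v = np.sort(st.centroids)
        assert abs(v[0] - TWO_POP["mean_a"]) < 10 and abs(v[1] - TWO_POP["mean_b"]) < 10

    def test_kfcm_two_population_recovery(self):
        st = run_kfcm(two_population_volume(), ClusterParams(c=2), OPERATOR2)
        v = np.sort(st.centroids)
        assert abs(v[0] - TWO_POP["mean_a"]) < 10 and abs(v[1] - TWO_POP["mean_b"]) < 10

    def test_fcm_objective_non_increasing(self):
        st = run_fcm(two_population_volume(), ClusterParams(c=2), InitSpec("random", seed=3))
        obj = np.array(st.objective_trace)
        assert np.all(np.diff(obj) <= 1e-6 * np.abs(obj[:-1]) + 1e-12)

    def test_fcm_fixed_point_consistency(self):
        vol = two_population_volume()
        st = run_fcm(vol, ClusterParams(c=2), OPERATOR2)
        want = fcm_memberships(vol.masked_intensities(), st.centroids, 2.0)
        np.testing.assert_allclose(st.memberships.values, want, atol=0)

    def test_kfcm_large_sigma_tracks_fcm(self):
        vol = two_population_volume()
        params = ClusterParams(c=2, kernel=KernelSpec(family="gaussian", sigma=1e6))
        st_k = run_kfcm(vol, params, OPERATOR2)
        st_f = run_fcm(vol, ClusterParams(c=2), OPERATOR2)
        np.testing.assert_allclose(st_k.centroids, st_f.centroids, atol=1e-3)

    @pytest.mark.parametrize("run", [run_fcm, run_kfcm, run_sfcm, run_skfcm, run_mskfcm])
    def test_repeat_runs_bitwise_identical(self, small_volume, run):
        params = ClusterParams(c=2, max_iter=20)
        init = InitSpec(mode="random", seed=11)
        a = run(small_volume, params, init)
        b = run(small_volume, params, init)
        assert np.array_equal(a.centroids, b.centroids)
        assert np.array_equal(a.memberships.values, b.memberships.values)
        assert a.objective_trace == b.objective_trace

    @pytest.mark.parametrize("run", [run_fcm, run_kfcm, run_sfcm, run_skfcm, run_mskfcm])
    def test_membership_invariants_and_centroid_range(self, small_volume_3d, run):
        params = ClusterParams(
            c=3, max_iter=30, neighborhood=NeighborhoodSpec(mode="3d", size=3)
        )
        st = run(small_volume_3d, params, InitSpec(mode="random", seed=5))
        st.memberships.validate(atol=1e-9)
        x = small_volume_3d.voxels
        assert np.all(st.centroids >= x.min()) and np.all(st.centroids <= x.max())
        assert st.iterations <= params.max_iter

    def test_nonconvergence_returns_state(self, small_volume):
        st = run_fcm(small_volume, ClusterParams(c=3, epsilon=1e-15, max_iter=3),
                     InitSpec(mode="random", seed=2))
        assert st.iterations == 3 and not st.converged


class TestReductions:
    def test_sfcm_p1_q0_equals_fcm(self, small_volume):
        params = ClusterParams(c=2, p=1.0, q=0.0, max_iter=40)
        init = InitSpec(mode="random", seed=9)
        a = run_sfcm(small_volume, params, init)
        b = run_fcm(small_volume, params, init)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.centroid_trace == b.centroid_trace
        np.testing.assert_allclose(a.memberships.values, b.memberships.values, atol=0)

    def test_mskfcm_p1_q0_equals_kfcm(self, small_volume):
        params = ClusterParams(c=2, p=1.0, q=0.0, max_iter=40)
        init = InitSpec(mode="random", seed=9)
        a = run_mskfcm(small_volume, params, init)
        b = run_kfcm(small_volume, params, init)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.centroid_trace == b.centroid_trace

    def test_skfcm_small_alpha_tracks_kfcm(self):
        """Continuity in alpha: the fixed-point shift vanishes linearly as
        the penalty weight goes to zero."""
        rng = np.random.default_rng(12)
        vol = ImageVolume(voxels=rng.uniform(-900, 50, (1, 16, 16)))
        kern = KernelSpec(family="gaussian", sigma=300.0, variance_scale="sigma2")
        init = InitSpec(mode="random", seed=4)
        b = run_kfcm(vol, ClusterParams(c=2, kernel=kern, epsilon=1e-10), init)
        gaps = {}
        for alpha in (1e-3, 1e-4):
            a = run_skfcm(
                vol, ClusterParams(c=2, alpha=alpha, kernel=kern, epsilon=1e-10), init
            )
            gaps[alpha] = float(np.max(np.abs(a.centroids - b.centroids)))
        assert gaps[1e-3] < 0.1
        assert gaps[1e-4] < 1e-2
        assert 5.0 < gaps[1e-3] / gaps[1e-4] < 20.0  # ~linear in alpha

    def test_skfcm_two_region_recovery(self):
        spec = PhantomSpec(shape=(1, 32, 32), nodules=(), vessels=(), noise_sd=20.0, seed=5)
        vol, _, _ = generate_phantom(spec)
        vol = ImageVolume(voxels=vol.voxels)  # cluster the full slice: lung vs wall
        params = ClusterParams(c=2, alpha=0.15,
                               kernel=KernelSpec(sigma=300.0, variance_scale="sigma2"))
        st = run_skfcm(vol, params, InitSpec(mode="operator", samples=((-850.0,), (40.0,))))
        v = np.sort(st.centroids)
        assert abs(v[0] - (-850.0)) < 15 and abs(v[1] - 40.0) < 15


class TestThreeDNeighborhoods:
    def test_replicated_slices_make_3d_equal_2d(self):
        """A depth-3 volume of identical slices: a 3x3x3 window sees each
        neighbor membership three times, so the spatial ratio u^p h^q is
        unchanged and the middle slice labels match the 2D run."""
        rng = np.random.default_rng(21)
        sl = rng.uniform(-900, 50, (16, 16))
        vol3 = ImageVolume(voxels=np.stack([sl, sl, sl]))
        vol2 = ImageVolume(voxels=sl[np.newaxis])
        init = InitSpec(mode="random", seed=8)
        p3 = ClusterParams(c=2, neighborhood=NeighborhoodSpec(mode="3d", size=3))
        p2 = ClusterParams(c=2, neighborhood=NeighborhoodSpec(mode="2d", size=3))
        st3 = run_mskfcm(vol3, p3, init)
        st2 = run_mskfcm(vol2, p2, init)
        labels3 = st3.labels()[1]
        labels2 = st2.labels()[0]
        assert np.array_equal(labels3, labels2)


class TestSelectNoduleCluster:
    def _state(self, centroids):
        from fuzzyroi import ClusterState, MembershipMatrix
        c = len(centroids)
        mm = MembershipMatrix(values=np.full((c, 1), 1.0 / c),
                              voxel_index=np.array([0]), shape=(1, 1, 1))
        return ClusterState(centroids=np.array(centroids), memberships=mm,
                            iterations=1, converged=True)

    def test_hint_picks_nearest_centroid(self):
        st = self._state([-850.0, -40.0, 60.0])
        assert select_nodule_cluster(st, hint=[-35.0]) == 1

    def test_three_clusters_default_to_middle(self):
        st = self._state([-40.0, 800.0, -850.0])
        assert select_nodule_cluster(st) == 0  # -40 is the midrange centroid

    def test_other_counts_require_hint(self):
        st = self._state([-850.0, 40.0])
        with pytest.raises(ParameterError):
            select_nodule_cluster(st)

    def test_phantom_selection_has_best_truth_overlap(self, standard_phantom):
        vol, truth, _ = standard_phantom
        st = run_mskfcm(vol, ClusterParams(c=3), InitSpec(mode="random", seed=1))
        sel = select_nodule_cluster(st)
        labels = st.labels()
        overlaps = [
            np.count_nonzero((labels == i) & truth.grid) for i in range(3)
        ]
        assert sel == int(np.argmax(overlaps))
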