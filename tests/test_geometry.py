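"""Manifold geometry: PCA, Procrustes, remapping vectors, subspaces."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from ringremap import geometry as geo
from ringremap.session import MapTuning
from ringremap.taskgen import TWO_PI


def ring_tuning(n_bins=50, n_units=12, radius=1.0, center=None, seed=0,
                noise=0.0):
    """Planted ring embedded in the first two of n_units dimensions."""
    rng = np.random.default_rng(seed)
    theta = (np.arange(n_bins) + 0.5) * TWO_PI / n_bins
    x = np.zeros((n_bins, n_units))
    x[:, 0] = radius * np.sin(theta)
    x[:, 1] = radius * np.cos(theta)
    if center is not None:
        x += center
    if noise:
        x += noise * rng.normal(size=x.shape)
    return x


def make_tuning(maps):
    arr = np.stack(maps)
    p = arr.shape[1]
    return MapTuning(tuning=arr, bin_centers=(np.arange(p) + 0.5) * TWO_PI / p,
                     maps=np.arange(arr.shape[0]))


class TestPcaVariance:
    def test_rank_one(self):
        u = np.outer(np.linspace(-1, 1, 30), np.ones(5))
        curve = geo.pca_variance(u)
        assert np.isclose(curve[0], 1.0)
        assert np.all(np.diff(curve) >= -1e-12)
        assert np.isclose(curve[-1], 1.0)

    def test_isotropic_gaussian_thirds(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20000, 3))
        curve = geo.pca_variance(x)
        ratios = np.diff(np.concatenate([[0], curve]))
        assert np.allclose(ratios, 1 / 3, atol=0.02)


class TestProcrustes:
    def test_identical_manifolds_score_zero(self):
        a = ring_tuning()
        res = geo.procrustes_misalignment(a, a.copy(), n_shuffle=50,
                                          rng=np.random.default_rng(0))
        assert res.rmse_observed < 1e-12
        assert res.rmse_optimal < 1e-12
        assert abs(res.score) < 1e-6

    def test_planted_rotation_recovered(self):
        rng = np.random.default_rng(1)
        a = ring_tuning(n_units=8, noise=0.05, seed=2)
        q = special_ortho_group.rvs(8, random_state=rng)
        b = a @ q.T
        res = geo.procrustes_misalignment(a, b, n_shuffle=100, rng=rng)
        assert res.rmse_optimal < 1e-10
        # the recovered rotation undoes the planted one on the centered data
        ac = (a - a.mean(0)) / np.linalg.norm(a - a.mean(0))
        bc = (b - b.mean(0)) / np.linalg.norm(b - b.mean(0))
        assert np.allclose(bc @ res.rotation, ac, atol=1e-8)

    def test_invariance_to_common_rotation(self):
        rng = np.random.default_rng(3)
        a = ring_tuning(n_units=10, noise=0.1, seed=4)
        b = ring_tuning(n_units=10, noise=0.1, seed=5)
        q = special_ortho_group.rvs(10, random_state=rng)
        r1 = geo.procrustes_misalignment(a, b, n_shuffle=200,
                                         rng=np.random.default_rng(9))
        r2 = geo.procrustes_misalignment(a @ q.T, b @ q.T, n_shuffle=200,
                                         rng=np.random.default_rng(9))
        assert np.isclose(r1.rmse_observed, r2.rmse_observed, atol=1e-10)
        assert np.isclose(r1.rmse_optimal, r2.rmse_optimal, atol=1e-10)
        # same-seed nulls differ only through the basis; quantiles agree
        assert np.isclose(r1.score, r2.score, rtol=0.05, atol=0.02)

    def test_random_rotation_scores_near_null(self):
        # a manifold rotated by a Haar rotation is a draw from the null
        rng = np.random.default_rng(6)
        a = ring_tuning(n_units=16, noise=0.05, seed=7)
        scores = []
        for i in range(5):
            q = special_ortho_group.rvs(16, random_state=rng)
            res = geo.procrustes_misalignment(a, a @ q.T, n_shuffle=200,
                                              rng=rng)
            scores.append(res.score)
        # p=0.25 of the null maps to score 1: draws straddle 1
        assert np.median(scores) > 0.5

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            geo.procrustes_misalignment(np.ones((2, 4)), np.ones((2, 4)))
        with pytest.raises(ValueError):
            geo.procrustes_misalignment(np.ones((5, 4)), np.ones((5, 3)))


class TestRemapVectors:
    def w_for(self, n_units):
        w = np.zeros((2, n_units))
        w[0, 0] = w[1, 1] = 1.0
        return w

    def test_pure_translation_in_nullspace(self):
        n = 10
        w = self.w_for(n)
        v0 = np.zeros(n)
        v0[5] = 2.0  # translation invisible to the decoder
        a = ring_tuning(n_units=n, seed=0)
        tun = make_tuning([a, a + v0])
        res = geo.remap_vectors(tun, w, n_shuffle=30,
                                rng=np.random.default_rng(0))
        assert np.allclose(res.ideal, v0, atol=1e-12)
        assert np.allclose(res.deviation, 0.0, atol=1e-9)
        assert np.allclose(res.w_residual, 0.0, atol=1e-12)
        # centered remapping vectors vanish entirely
        assert np.allclose(res.xi - res.ideal, 0.0, atol=1e-12)

    def test_planted_two_dim_residual_spectrum(self):
        n, p = 12, 60
        w = self.w_for(n)
        a = ring_tuning(n_bins=p, n_units=n, seed=1)
        theta = (np.arange(p) + 0.5) * TWO_PI / p
        v0 = np.zeros(n)
        v0[6] = 3.0
        resid = np.zeros((p, n))
        resid[:, 7] = 0.3 * np.sin(theta)   # 2D sinusoidal residual
        resid[:, 8] = 0.3 * np.cos(theta)
        tun = make_tuning([a, a + v0 + resid])
        res = geo.remap_vectors(tun, w, n_shuffle=20,
                                rng=np.random.default_rng(1))
        # xi spectrum concentrates on exactly 2 components
        assert res.variance_spectrum[1] > 0.999
        assert res.variance_spectrum[0] < 0.9

    def test_nullspace_null_preserves_decoding_but_misaligns(self):
        n = 16
        w = self.w_for(n)
        rng = np.random.default_rng(2)
        a = ring_tuning(n_units=n, seed=3, noise=0.02)
        b = a + 1.5 * (np.arange(n) == 8)
        tun = make_tuning([a, b])
        res = geo.remap_vectors(tun, w, n_shuffle=50, rng=rng)
        # observed deviation (aligned maps) far below the nullspace null
        assert res.deviation.mean() < np.quantile(
            res.null_deviation.mean(axis=1), 0.025)
        # nullspace rotations cannot change the decoded positions...
        # (their W-residual equals the observed one by construction), while
        # full rotations break the decoder badly:
        assert res.null_w_residual.mean() > 100 * max(res.w_residual.mean(),
                                                      1e-12)


class TestSubspaces:
    def test_planted_plane_recovered(self):
        n = 20
        a = ring_tuning(n_units=n, seed=0, noise=0.001)
        tun = make_tuning([a])
        basis = geo.position_subspace(tun, scope="per-map", map_index=0)
        assert basis.shape == (n, 2)
        assert np.allclose(basis.T @ basis, np.eye(2), atol=1e-10)
        plane = np.zeros((n, 2))
        plane[0, 0] = plane[1, 1] = 1.0
        assert geo.subspace_alignment(basis, plane) > 0.999
        # both columns essentially inside the embedding plane
        assert geo.cosine_to_subspace(basis[:, 0], plane) > 0.999
        assert geo.cosine_to_subspace(basis[:, 1], plane) > 0.999

    def test_translation_orthogonal_to_position_plane(self):
        n = 10
        a = ring_tuning(n_units=n, seed=1)
        v0 = 2.0 * (np.arange(n) == 7)
        tun = make_tuning([a, a + v0])
        basis = geo.position_subspace(tun, scope="across")
        d = geo.remap_dimension(tun, 0, 1)
        assert np.allclose(d, (np.arange(n) == 7).astype(float))
        assert geo.cosine_to_subspace(d, basis) < 1e-8

    def test_remap_dimension_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(30, 6))
        b = rng.normal(size=(30, 6))
        tun = make_tuning([a, b])
        d = geo.remap_dimension(tun, 0, 1)
        expect = b.mean(0) - a.mean(0)
        expect /= np.linalg.norm(expect)
        assert np.allclose(d, expect, atol=1e-12)
        assert np.isclose(np.linalg.norm(d), 1.0)
        with pytest.raises(ValueError):
            geo.remap_dimension(tun, 1, 1)
        with pytest.raises(ValueError):
            geo.remap_dimension(make_tuning([a, a.copy()]), 0, 1)

    def test_cosine_to_subspace_cases(self):
        basis = np.zeros((8, 2))
        basis[0, 0] = basis[3, 1] = 1.0
        inside = 0.7 * basis[:, 0] - 0.2 * basis[:, 1]
        assert np.isclose(geo.cosine_to_subspace(inside, basis), 1.0)
        ortho = (np.arange(8) == 5).astype(float)
        assert np.isclose(geo.cosine_to_subspace(ortho, basis), 0.0)
        rng = np.random.default_rng(3)
        v = rng.normal(size=8)
        proj = basis @ basis.T  # explicit projector oracle
        assert np.isclose(geo.cosine_to_subspace(v, basis),
                          np.linalg.norm(proj @ v) / np.linalg.norm(v))
        with pytest.raises(ValueError):
            geo.cosine_to_subspace(np.zeros(8), basis)

    def test_random_cosine_null_beta_law(self):
        # cos^2 of a random unit vector onto a 2D plane in R^n ~ Beta(1, n/2-1)
        n = 64
        basis = np.eye(n)[:, :2]
        c = geo.random_cosine_null(basis, n_samples=20000,
                                   rng=np.random.default_rng(4))
        assert np.isclose((c ** 2).mean(), 2 / n, atol=0.005)


class TestRemapAngles:
    def centroids_tuning(self, centroids, n_units):
        maps = []
        for c in centroids:
            vec = np.zeros(n_units)
            vec[:len(c)] = c
            maps.append(ring_tuning(n_units=n_units, radius=0.1, seed=1)
                        + vec)
        return make_tuning(maps)

    def test_equilateral_triangle_60(self):
        h = np.sqrt(3) / 2
        tun = self.centroids_tuning([[0, 0, 0], [1, 0, 0], [0.5, h, 0]],
                                    n_units=8)
        angles = geo.remap_dim_angles(tun)
        assert len(angles) == 3
        assert np.allclose(list(angles.values()), 60.0, atol=1e-6)

    def test_regular_tetrahedron_angles(self):
        # acute angles between the 6 edge directions of a regular
        # tetrahedron: 60 deg for edges sharing a vertex (12 pairs),
        # 90 deg for the 3 opposite-edge pairs
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                         dtype=float)
        tun = self.centroids_tuning(list(verts), n_units=9)
        angles = geo.remap_dim_angles(tun)
        vals = np.array(sorted(angles.values()))
        assert len(vals) == 15
        assert np.allclose(vals[:12], 60.0, atol=1e-6)
        assert np.allclose(vals[12:], 90.0, atol=1e-6)

    def test_needs_three_maps(self):
        with pytest.raises(ValueError):
            geo.remap_dim_angles(make_tuning([ring_tuning(), ring_tuning()]))


class TestTorusSlices:
    def test_separable_activity_slices(self):
        px, py, n = 12, 16, 5
        fx = np.linspace(1, 2, px)
        gy = np.sin(np.linspace(0, TWO_PI, py, endpoint=False)) + 2
        unit_scale = np.arange(1, n + 1, dtype=float)
        tuning = fx[:, None, None] * gy[None, :, None] * unit_scale
        # slice at fixed x is proportional to g(y)
        s = geo.torus_slices(tuning, "x", 3)
        assert s.shape == (py, n)
        ratio = s[:, 0] / gy
        assert np.allclose(ratio, ratio[0])
        # slice at fixed y proportional to f(x)
        s2 = geo.torus_slices(tuning, "y", 5)
        ratio2 = s2[:, 2] / fx
        assert np.allclose(ratio2, ratio2[0])
        # slicing stored bins returns them exactly
        assert np.array_equal(s, tuning[3])

    def test_level_out_of_range(self):
        with pytest.raises(ValueError):
            geo.torus_slices(np.zeros((4, 4, 2)), "x", 4)
        with pytest.raises(ValueError):
            geo.torus_slices(np.zeros((4, 4, 2)), "z", 0)
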