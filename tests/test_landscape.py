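"""Landscape statistics: PCA, distances, MRM, centroid regressions."""

import numpy as np
import pytest

from minsamp import (PopMetadata, cah_regression, centroid_distances,
                     distance_matrices, env_pc1, mrm)
from minsamp.landscape import haversine_matrix, mrm_fit_only


def make_meta(coords, env, planar=True):
    return PopMetadata(pop_ids=[f"p{i}" for i in range(len(coords))],
                       coords=np.asarray(coords, dtype=float),
                       env=np.asarray(env, dtype=float), planar=planar)


class TestEnvPc1:
    def test_perfectly_correlated_variables(self):
        x = np.linspace(0, 1, 6)
        env = np.column_stack([x, 2 * x + 1])
        scores, loadings, explained = env_pc1(env, return_model=True)
        assert explained == pytest.approx(1.0)

    def test_one_dimensional_data_scores_equal_centered_values(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        env = np.column_stack([x, np.full(4, 3.0) + 1e-9 * np.arange(4)])
        scores = env_pc1(env, scale=False)
        centered = x - x.mean()
        assert np.allclose(np.abs(scores), np.abs(centered), atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        env = rng.normal(size=(5, 19))
        scores = env_pc1(env)
        X = (env - env.mean(0)) / env.std(0, ddof=1)
        w, v = np.linalg.eigh(np.cov(X, rowvar=False))
        pc1 = X @ v[:, -1]
        assert (np.allclose(scores, pc1, atol=1e-8)
                or np.allclose(scores, -pc1, atol=1e-8))

    def test_zero_variance_variable_dropped(self):
        env = np.column_stack([np.arange(5.0), np.full(5, 7.0),
                               np.arange(5.0) ** 2])
        with pytest.warns(UserWarning):
            scores = env_pc1(env)
        assert np.isfinite(scores).all()


class TestDistances:
    def test_identical_coordinates_zero_distance(self):
        meta = make_meta([(1, 1), (1, 1), (0, 0)], np.random.default_rng(0).normal(size=(3, 2)))
        dm = distance_matrices(meta, np.zeros((3, 3)))
        assert dm.geographic[0, 1] == 0

    def test_haversine_quarter_meridian(self):
        d = haversine_matrix(np.array([[0.0, 0.0], [0.0, 90.0]]))
        assert d[0, 1] == pytest.approx(10007.5, abs=1.0)

    def test_env_distance_absolute_pc1_difference(self):
        meta = make_meta([(0, 0), (1, 0)], [[0.0, 0.0], [1.0, 1.0]])
        meta.pc1 = np.array([1.0, -0.5])
        dm = distance_matrices(meta, np.zeros((2, 2)))
        assert dm.environmental[0, 1] == pytest.approx(1.5)

    def test_pop_id_mismatch_names_offenders(self):
        meta = make_meta([(0, 0), (1, 0), (2, 0)],
                         np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(ValueError, match="px"):
            distance_matrices(meta, np.zeros((3, 3)),
                              pop_ids=["p0", "p1", "px"])


class TestMrm:
    def _matrices(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(n, 2))
        geo = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        e = rng.normal(size=n)
        env = np.abs(e[:, None] - e[None])
        return geo, env

    def test_exact_coefficient_recovery(self):
        geo, env = self._matrices()
        gen = 0.5 * geo + 0.0 * env
        res = mrm(gen, geo, env, n_permutations=50, seed=1)
        assert res.beta_geo == pytest.approx(0.5, abs=1e-10)
        assert res.beta_env == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_zero_response_zero_betas(self):
        geo, env = self._matrices(seed=2)
        res = mrm(np.zeros_like(geo), geo, env, n_permutations=20, seed=1)
        assert res.beta_geo == 0 and res.beta_env == 0

    def test_single_predictor_equals_simple_ols(self):
        from scipy import stats as sps

        geo, _ = self._matrices(seed=3)
        rng = np.random.default_rng(4)
        gen = 0.3 * geo + rng.normal(0, 0.1, size=geo.shape)
        gen = (gen + gen.T) / 2
        np.fill_diagonal(gen, 0)
        res = mrm_fit_only(gen, geo)            # single-predictor MRM
        i, j = np.tril_indices(geo.shape[0], k=-1)
        slope = sps.linregress(geo[i, j], gen[i, j]).slope
        assert res.beta_geo == pytest.approx(slope, abs=1e-10)

    def test_collinear_predictors_rejected(self):
        geo, _ = self._matrices(seed=5)
        with pytest.raises(ValueError):
            mrm(geo, geo, 2 * geo, n_permutations=10, seed=1)

    def test_permutation_p_floor(self):
        geo, env = self._matrices(seed=6)
        gen = 0.5 * geo
        res = mrm(gen, geo, env, n_permutations=100, seed=1)
        assert res.p_geo >= 1 / 100

    def test_relabeling_invariance(self):
        """Permutation p-values do not depend on population labels."""
        geo, env = self._matrices(n=7, seed=7)
        rng = np.random.default_rng(8)
        gen = 0.2 * geo + 0.1 * env + rng.normal(0, 0.05, size=geo.shape)
        gen = (gen + gen.T) / 2
        np.fill_diagonal(gen, 0)
        res1 = mrm(gen, geo, env, n_permutations=200, seed=9)
        perm = np.random.default_rng(10).permutation(7)
        res2 = mrm(gen[np.ix_(perm, perm)], geo[np.ix_(perm, perm)],
                   env[np.ix_(perm, perm)], n_permutations=200, seed=9)
        assert res1.beta_geo == pytest.approx(res2.beta_geo, abs=1e-12)
        assert abs(res1.p_geo - res2.p_geo) <= 0.06


class TestCentroids:
    def test_two_points(self):
        meta = make_meta([(0, 0), (2, 0)],
                         [[0.0, 1.0], [1.0, 0.0]])
        out = centroid_distances(meta)
        assert np.allclose(out.geo_centroid_dist, [1.0, 1.0])

    def test_all_identical_zero(self):
        meta = make_meta([(3, 3)] * 4, np.ones((4, 2)))
        out = centroid_distances(meta)
        assert np.allclose(out.geo_centroid_dist, 0)
        assert np.allclose(out.niche_centroid_dist, 0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(5, 2))
        env = rng.normal(size=(5, 4))
        meta = make_meta(coords, env)
        out = centroid_distances(meta, n_niche_pcs=2)
        ref_geo = np.sqrt(((coords - coords.mean(0)) ** 2).sum(1))
        assert np.allclose(out.geo_centroid_dist, ref_geo, atol=1e-10)
        X = (env - env.mean(0)) / env.std(0, ddof=1)
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        niche = u[:, :2] * s[:2]
        ref_niche = np.sqrt(((niche - niche.mean(0)) ** 2).sum(1))
        assert np.allclose(out.niche_centroid_dist, ref_niche, atol=1e-8)


class TestCah:
    def test_exact_linear_recovery(self):
        d = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        hs = 0.5 - 0.1 * d
        res = cah_regression(hs, d)
        assert res.slope == pytest.approx(-0.1, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_response_zero_slope(self):
        res = cah_regression(np.full(5, 0.3), np.arange(5.0))
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            cah_regression(np.arange(5.0), np.ones(5))


def test_mrm_power_on_ibd_ground_truth(ibd_dataset):
    """Distance-decayed migration plants true IBD: the MRM geographic
    coefficient is positive and significant on the seeded dataset."""
    from minsamp import pairwise_fst

    ds, meta = ibd_dataset
    fst = pairwise_fst(ds, "wc")
    meta2 = centroid_distances(meta)
    dm = distance_matrices(meta2, fst)
    res = mrm(dm.genetic, dm.geographic, dm.environmental,
              n_permutations=500, seed=3)
    assert res.beta_geo > 0
    assert res.p_geo < 0.05
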