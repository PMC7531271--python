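"""Outlier scan: BH correction, null calibration, planted ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minsamp import (GenotypeDataset, detect_outliers, env_association_test,
                     fst_outlier_test, locus_fst_scan, plant_env_clines)
from minsamp.datasets import PoolFrequencyDataset
from minsamp.outliers import benjamini_hochberg

from conftest import random_snp_dataset
from oracles import oracle_wc_theta_counts


class TestBenjaminiHochberg:
    def test_monotone_in_p_rank(self):
        p = np.array([0.001, 0.5, 0.01, 0.9, 0.04])
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        q = benjamini_hochberg(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)

    @given(st.lists(st.floats(0.0001, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_q_at_least_p(self, ps):
        p = np.array(ps)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()


class TestLocusScan:
    def test_identical_frequencies_theta_near_zero(self):
        rng = np.random.default_rng(1)
        g = (rng.random((40, 30, 2)) < 0.4).astype(np.int16)
        ds = GenotypeDataset(genotypes=g,
                             sample_pop=np.repeat(np.arange(4), 10),
                             pop_ids=list("abcd"),
                             locus_ids=[f"l{i}" for i in range(30)],
                             kind="snp")
        _, global_theta = locus_fst_scan(ds)
        assert abs(global_theta) < 0.05

    def test_fixed_locus_attains_max(self, structured):
        ds, _ = structured
        g = ds.genotypes.copy()
        # plant a locus fixed for alternative alleles between clusters
        cluster = (ds.sample_pop < 8).astype(np.int16)
        g[:, 0, 0] = cluster
        g[:, 0, 1] = cluster
        planted = GenotypeDataset(genotypes=g, sample_pop=ds.sample_pop.copy(),
                                  pop_ids=list(ds.pop_ids),
                                  locus_ids=list(ds.locus_ids), kind="snp")
        per_locus, _ = locus_fst_scan(planted)
        assert np.nanargmax(per_locus) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_pooled_theta_matches_count_oracle(self, seed):
        from minsamp import pool_frequencies

        ds = random_snp_dataset(seed + 50, missing_prob=0.0)
        pool = pool_frequencies(ds)
        per_locus, _ = locus_fst_scan(pool)
        ft_n = 2 * ds.pop_sizes()
        for l in range(ds.n_loci):
            p = pool.counts[:, l, 1] / pool.counts[:, l].sum(axis=1)
            ref = oracle_wc_theta_counts(list(pool.counts[:, l].sum(axis=1)),
                                         list(p))
            if np.isfinite(ref):
                assert per_locus[l] == pytest.approx(ref, abs=1e-10)


def _null_pool_dataset(n_loci, n_pops, theta, seed, n_hap=30):
    """Pooled dataset drawn exactly from the beta-binomial null."""
    rng = np.random.default_rng(seed)
    pbar = rng.uniform(0.1, 0.9, size=n_loci)
    a = pbar * (1 - theta) / theta
    b = (1 - pbar) * (1 - theta) / theta
    pf = rng.beta(a, b, size=(n_pops, n_loci))
    counts1 = rng.binomial(n_hap, pf)
    counts = np.stack([n_hap - counts1, counts1], axis=2)
    av = np.tile(np.array([0, 1], dtype=np.int16), (n_loci, 1))
    return PoolFrequencyDataset(counts=counts, allele_values=av,
                                pop_ids=[f"p{i}" for i in range(n_pops)],
                                locus_ids=[f"l{i}" for i in range(n_loci)])


class TestDifferentiationTest:
    def test_null_calibration_few_flags(self):
        """Data simulated from the null itself: BH q < 0.05 flags ~ 0."""
        ds = _null_pool_dataset(500, 12, theta=0.1, seed=3)
        p, q, status = fst_outlier_test(ds, n_null=400, seed=4)
        assert status == "ok"
        assert (q < 0.05).sum() <= 2

    def test_observed_fdr_controlled(self):
        ds = _null_pool_dataset(500, 10, theta=0.15, seed=5)
        p, q, _ = fst_outlier_test(ds, n_null=400, seed=6)
        # valid p-values: roughly uniform, mean near 0.5
        assert 0.4 < np.nanmean(p) < 0.6

    def test_p_floor(self):
        ds = _null_pool_dataset(50, 8, theta=0.1, seed=7)
        p, _, _ = fst_outlier_test(ds, n_null=200, seed=8)
        assert np.nanmin(p) >= 1 / 201


class TestEnvAssociation:
    def test_linear_locus_has_minimal_p(self):
        rng = np.random.default_rng(9)
        S, L = 12, 60
        env = np.linspace(-1, 1, S)
        pf = rng.uniform(0.2, 0.8, size=(S, L))
        pf[:, 0] = 0.5 + 0.45 * env                 # exactly linear in env
        counts1 = rng.binomial(40, pf)
        counts = np.stack([40 - counts1, counts1], axis=2)
        av = np.tile(np.array([0, 1], dtype=np.int16), (L, 1))
        ds = PoolFrequencyDataset(counts=counts, allele_values=av,
                                  pop_ids=[f"p{i}" for i in range(S)],
                                  locus_ids=[f"l{i}" for i in range(L)])
        p, q = env_association_test(ds, env, n_permutations=300, seed=10)
        assert np.argmin(p) == 0

    def test_constant_env_rejected(self, structured):
        ds, _ = structured
        with pytest.raises(ValueError):
            env_association_test(ds, np.ones(ds.n_pops))

    def test_null_calibration(self):
        ds = _null_pool_dataset(400, 10, theta=0.1, seed=11)
        env = np.random.default_rng(12).normal(size=10)
        p, q = env_association_test(ds, env, n_permutations=300, seed=13)
        assert (q < 0.05).sum() <= 2


class TestDetectOutliers:
    def test_zero_threshold_never_flags(self, structured):
        ds, meta = structured
        from minsamp import env_pc1

        env = env_pc1(meta.env)
        res = detect_outliers(ds.take_loci(np.arange(60)), env,
                              q_threshold=0.0, n_null=100,
                              n_permutations=100, seed=1)
        assert res.n_outliers == 0
        assert np.isfinite(res.max_fst)

    def test_planted_cline_flagged(self):
        """A strong environmental cline in a weakly structured background
        is recovered by the joint scan."""
        from minsamp import (build_hierarchical_model, env_pc1,
                             generate_landscape, simulate_snp_genotypes)

        model = build_hierarchical_model("high", n_old=6, n_young=6,
                                         ne_old=800, m_within=1e-3,
                                         f_sd=0.0, seed=21)
        meta, model = generate_landscape(model, mode="island", seed=22)
        ds = simulate_snp_genotypes(model, n_loci=200,
                                    n_diploids_per_pop=10, seed=23)
        env = env_pc1(meta.env)
        ds2, planted = plant_env_clines(ds, env, 5, seed=24, steepness=3.0)
        res = detect_outliers(ds2, env, n_null=1500, n_permutations=800,
                              seed=25)
        found = set(res.outlier_ids()) & set(planted)
        assert len(found) >= 3
        # background false positives stay rare
        background = set(res.outlier_ids()) - set(planted)
        assert len(background) <= 3
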