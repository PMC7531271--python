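"""Synthetic-data generator: model building, ascertainment, inbreeding."""

import numpy as np
import pytest
from scipy import stats as sps

from minsamp import (DemographicModel, build_hierarchical_model,
                     generate_landscape, pool_frequencies,
                     simulate_microsat_genotypes, simulate_snp_genotypes)
from minsamp.simulate import DEFAULTS


class TestBuildModel:
    def test_high_regime_defaults(self):
        m = build_hierarchical_model("high", seed=0)
        assert m.n_demes == 50 and m.n_old == 25
        # jittered around the regime mean, one tenth of within-cluster flow
        assert np.allclose(m.m_between.mean(), 0.0001, rtol=0.2)
        assert np.allclose(m.ne[:25].mean(), 5000, rtol=0.1)
        assert np.allclose(m.ne[25:].mean(), 5000 / 1.5, rtol=0.1)

    def test_low_regime_no_between_cluster_flow(self):
        m = build_hierarchical_model("low", seed=0)
        assert (m.m_between == 0).all()

    def test_zero_jitter_exact_means(self):
        m = build_hierarchical_model("high", jitter_cv=0.0, f_sd=0.0, seed=0)
        assert (m.ne[:25] == 5000).all()
        assert (m.m_within == 0.001).all()
        assert m.t_split == 20000 and m.t_ancestral == 140000

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_hierarchical_model("medium")
        with pytest.raises(ValueError):
            build_hierarchical_model("high", t_split=-5)
        with pytest.raises(ValueError):
            DemographicModel(n_old=2, n_young=2, ne=np.array([10., 10., 10., -1.]),
                             m_within=np.zeros(4), m_between=np.zeros(4),
                             t_split=10, t_ancestral=100, f=np.zeros(4))

    def test_serialization_roundtrip(self):
        m = build_hierarchical_model("high", seed=5)
        m2 = DemographicModel.from_dict(m.to_dict())
        assert np.allclose(m.ne, m2.ne) and m.t_split == m2.t_split

    def test_pairwise_migration_island_structure(self):
        m = build_hierarchical_model("high", n_old=3, n_young=3,
                                     jitter_cv=0.0, seed=0)
        M = m.pairwise_migration()
        assert M[0, 1] == pytest.approx(0.001)      # within old cluster
        assert M[0, 4] == pytest.approx(0.0001)     # between clusters
        assert (np.diag(M) == 0).all()


class TestSnpSimulation:
    def test_dimensions_and_polymorphism(self):
        m = build_hierarchical_model("high", n_old=3, n_young=3, ne_old=500,
                                     m_within=1e-4, seed=1)
        ds = simulate_snp_genotypes(m, n_loci=40, n_diploids_per_pop=5, seed=2)
        assert ds.genotypes.shape == (30, 40, 2)
        assert ds.n_pops == 6
        # ascertainment: every locus polymorphic in the total sample
        freq = ds.genotypes.sum(axis=(0, 2)) / (2 * ds.n_samples)
        assert ((freq > 0) & (freq < 1)).all()

    def test_reproducible_bit_identical(self):
        m = build_hierarchical_model("high", n_old=3, n_young=3, ne_old=500,
                                     m_within=1e-4, seed=1)
        a = simulate_snp_genotypes(m, 25, 4, seed=9)
        b = simulate_snp_genotypes(m, 25, 4, seed=9)
        assert np.array_equal(a.genotypes, b.genotypes)
        c = simulate_snp_genotypes(m, 25, 4, seed=10)
        assert not np.array_equal(a.genotypes, c.genotypes)

    def test_full_inbreeding_all_homozygous(self):
        m = build_hierarchical_model("high", n_old=3, n_young=3, ne_old=500,
                                     m_within=1e-4, f_sd=0.0, seed=1)
        m.f[:] = 1.0
        ds = simulate_snp_genotypes(m, 30, 5, seed=3)
        assert (ds.genotypes[:, :, 0] == ds.genotypes[:, :, 1]).all()

    def test_collapsed_and_exact_paths_agree(self):
        """The panmictic-limit collapse matches the structured simulation
        in distribution: compare mean Hs and FST at matched parameters."""
        from minsamp import basic_stats
        from minsamp import simulate as sim

        m = build_hierarchical_model("high", n_old=6, n_young=6, ne_old=2000,
                                     ne_ratio=1.0, m_within=0.005,
                                     m_between=0.002, f_sd=0.0, seed=4)
        assert m.collapsible()
        ds_c = simulate_snp_genotypes(m, 150, 8, seed=5)
        try:
            sim.COLLAPSE_NM, keep = np.inf, sim.COLLAPSE_NM
            assert not m.collapsible()
            ds_e = simulate_snp_genotypes(m, 150, 8, seed=5)
        finally:
            sim.COLLAPSE_NM = keep
        st_c, st_e = basic_stats(ds_c), basic_stats(ds_e)
        assert st_c.mean_hs == pytest.approx(st_e.mean_hs, abs=0.03)
        assert st_c.fst_overall == pytest.approx(st_e.fst_overall, abs=0.02)


class TestMicrosatSimulation:
    def test_zero_mutation_rate_monomorphic(self):
        m = build_hierarchical_model("high", n_old=3, n_young=3, ne_old=500,
                                     m_within=1e-4, f_sd=0.0, seed=1)
        ds = simulate_microsat_genotypes(m, n_loci=6, mutation_rate=0.0,
                                         n_diploids_per_pop=4, seed=2)
        assert (ds.genotypes == ds.genotypes[0, 0, 0]).all()

    def test_requested_locus_count(self):
        m = build_hierarchical_model("high", n_old=3, n_young=3, ne_old=500,
                                     m_within=1e-4, seed=1)
        ds = simulate_microsat_genotypes(m, n_loci=22, mutation_rate=5e-4,
                                         n_diploids_per_pop=4, seed=2)
        assert ds.n_loci == 22 and ds.kind == "microsat"
        for l in range(22):
            assert len(np.unique(ds.genotypes[:, l, :])) >= 1

    def test_high_rate_approaches_smm_equilibrium(self):
        """Single large deme: Hs near the stepwise-mutation equilibrium
        1 - 1/sqrt(1 + 8 Ne mu)."""
        from minsamp import basic_stats

        ne, mu = 2000.0, 2e-4
        m = build_hierarchical_model("high", n_old=2, n_young=2, ne_old=ne,
                                     ne_ratio=1.0, m_within=0.1, f_sd=0.0,
                                     t_split=4e6, t_ancestral=8e6, seed=1)
        ds = simulate_microsat_genotypes(m, n_loci=120, mutation_rate=mu,
                                         n_diploids_per_pop=10, seed=3)
        expected = 1 - 1 / np.sqrt(1 + 8 * ne * mu)
        st = basic_stats(ds)
        # migration 0.1 makes the 4 demes one pool of 4*Ne: adjust
        expected_pool = 1 - 1 / np.sqrt(1 + 8 * 4 * ne * mu)
        assert st.mean_hs == pytest.approx(expected_pool, abs=0.08)


class TestPooling:
    def test_direct_counts(self):
        from minsamp.datasets import GenotypeDataset

        g = np.array([[(0, 0)], [(0, 1)]], dtype=np.int16)
        ds = GenotypeDataset(genotypes=g, sample_pop=np.zeros(2, dtype=int),
                             pop_ids=["p0"], locus_ids=["l0"], kind="snp")
        pool = pool_frequencies(ds)
        assert pool.counts[0, 0, 0] == 3 and pool.counts[0, 0, 1] == 1

    def test_all_missing_total_zero(self):
        from minsamp.datasets import MISSING, GenotypeDataset

        g = np.full((2, 1, 2), MISSING, dtype=np.int16)
        ds = GenotypeDataset(genotypes=g, sample_pop=np.zeros(2, dtype=int),
                             pop_ids=["p0"], locus_ids=["l0"], kind="snp")
        pool = pool_frequencies(ds)
        assert pool.totals()[0, 0] == 0


class TestLandscapeModes:
    def test_island_leaves_model_unchanged(self):
        m = build_hierarchical_model("high", n_old=4, n_young=4, seed=1)
        meta, m2 = generate_landscape(m, mode="island", seed=2)
        assert m2 is m
        assert meta.planar and meta.env.shape == (8, 3)

    def test_ibd_sigma_infinite_reduces_to_uniform(self):
        m = build_hierarchical_model("high", n_old=4, n_young=4,
                                     jitter_cv=0.0, seed=1)
        meta, m2 = generate_landscape(m, mode="ibd", seed=2, sigma_ibd=1e12)
        M = m2.migration_matrix
        off = M[~np.eye(8, dtype=bool)]
        assert np.allclose(off, off[0], rtol=1e-6)

    def test_cah_spearman_minus_one(self):
        m = build_hierarchical_model("high", n_old=4, n_young=4, seed=1)
        meta, m2 = generate_landscape(m, mode="cah", seed=2)
        d = np.linalg.norm(meta.coords - meta.coords.mean(axis=0), axis=1)
        rho = sps.spearmanr(m2.ne, d).statistic
        assert rho == pytest.approx(-1.0)

    def test_unknown_mode_rejected(self):
        m = build_hierarchical_model("high", n_old=4, n_young=4, seed=1)
        with pytest.raises(ValueError):
            generate_landscape(m, mode="torus", seed=2)
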