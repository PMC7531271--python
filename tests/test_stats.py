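"""Estimator correctness against hand evaluation and naive oracles."""

import numpy as np
import pandas as pd
import pytest

from minsamp import (GenotypeDataset, MISSING, allele_frequencies, basic_stats,
                     fis_nan_correlation, pairwise_fst, pool_frequencies)
from minsamp.datasets import PoolFrequencyDataset

from conftest import random_microsat_dataset, random_snp_dataset
from oracles import oracle_basic_stats, oracle_wc_pair_theta


def one_pop_dataset(genotypes):
    g = np.array(genotypes, dtype=np.int16)[:, None, :]
    return GenotypeDataset(genotypes=g, sample_pop=np.zeros(len(genotypes), dtype=int),
                           pop_ids=["p0"], locus_ids=["l0"], kind="snp")


class TestAlleleFrequencies:
    def test_direct_count(self):
        ds = one_pop_dataset([(0, 0), (0, 1), (1, 1), (0, 1)])
        ft = allele_frequencies(ds)
        assert ft.freqs[0, 0, 1] == pytest.approx(0.5)
        assert ft.n[0, 0] == 4

    def test_all_missing_cell(self):
        ds = one_pop_dataset([(MISSING, MISSING), (MISSING, MISSING)])
        ft = allele_frequencies(ds)
        assert ft.n[0, 0] == 0
        assert np.isnan(ft.freqs[0, 0]).all()

    def test_half_missing_genotype_excluded(self):
        ds = one_pop_dataset([(0, MISSING), (0, 1)])
        ft = allele_frequencies(ds)
        assert ft.n[0, 0] == 1
        assert ft.freqs[0, 0, 1] == pytest.approx(0.5)

    def test_pooled_counts(self):
        counts = np.array([[[3, 1]]])
        pool = PoolFrequencyDataset(counts=counts,
                                    allele_values=np.array([[0, 1]], dtype=np.int16),
                                    pop_ids=["p0"], locus_ids=["l0"])
        ft = allele_frequencies(pool)
        assert ft.freqs[0, 0, 1] == pytest.approx(0.25)
        assert ft.n[0, 0] == pytest.approx(2.0)       # 4 copies / 2


class TestBasicStats:
    def test_worked_example(self):
        # genotypes 0/0, 0/1, 1/1, 0/1: Ho = 0.5,
        # Hs = (4/3)(1 - 0.5 - 0.0625) = 0.58333, FIS = 1 - 0.5/0.58333
        ds = one_pop_dataset([(0, 0), (0, 1), (1, 1), (0, 1)])
        st = basic_stats(ds)
        assert st.ho[0, 0] == pytest.approx(0.5)
        assert st.hs[0, 0] == pytest.approx(0.5833333333, abs=1e-9)
        assert st.fis[0, 0] == pytest.approx(0.1428571428, abs=1e-9)

    def test_two_heterozygotes(self):
        ds = one_pop_dataset([(0, 1), (0, 1)])
        st = basic_stats(ds)
        assert st.ho[0, 0] == pytest.approx(1.0)
        assert st.hs[0, 0] == pytest.approx(0.5)
        assert st.fis[0, 0] == pytest.approx(-1.0)

    def test_monomorphic_cell_counts_as_nan(self):
        ds = one_pop_dataset([(0, 0), (0, 0), (0, 0)])
        st = basic_stats(ds)
        assert st.ho[0, 0] == 0
        assert st.hs[0, 0] == 0
        assert np.isnan(st.fis[0, 0])
        assert st.nan_fis_count[0] == 1

    def test_pooled_ho_unavailable(self):
        ds = random_snp_dataset(5)
        pool = pool_frequencies(ds)
        st = basic_stats(pool)
        assert not st.has_genotypes
        assert np.isnan(st.ho).all() and np.isnan(st.fis).all()
        assert np.isfinite(st.mean_hs)

    def test_fst_requires_two_pops(self):
        ds = random_snp_dataset(7).take_pops(np.array([0]))
        pool = pool_frequencies(ds)
        with pytest.raises(ValueError):
            basic_stats(pool)


@pytest.mark.parametrize("seed", range(30))
@pytest.mark.parametrize("maker", [random_snp_dataset, random_microsat_dataset])
def test_oracle_equivalence(maker, seed):
    """All per-cell and per-locus statistics match the naive per-term
    reference implementation to 1e-10 on random small datasets."""
    ds = maker(seed)
    st = basic_stats(ds)
    ref = oracle_basic_stats(ds)
    np.testing.assert_allclose(st.ho, np.array(ref["ho"]), atol=1e-10)
    np.testing.assert_allclose(st.hs, np.array(ref["hs"]), atol=1e-10)
    np.testing.assert_allclose(st.fis, np.array(ref["fis"]), atol=1e-10)
    np.testing.assert_allclose(st.ht, np.array(ref["ht"]), atol=1e-10)
    np.testing.assert_allclose(st.fst_per_locus, np.array(ref["fst_per_locus"]),
                               atol=1e-10)
    if np.isfinite(st.fst_overall):
        assert st.fst_overall == pytest.approx(ref["fst_overall"], abs=1e-10)


class TestPairwiseFst:
    def test_fixed_difference_gives_theta_one(self):
        g = np.array([[(0, 0)] * 3, [(0, 0)] * 3,
                      [(1, 1)] * 3, [(1, 1)] * 3], dtype=np.int16)
        ds = GenotypeDataset(genotypes=g, sample_pop=np.array([0, 0, 1, 1]),
                             pop_ids=["a", "b"], locus_ids=["l1", "l2", "l3"],
                             kind="snp")
        pw = pairwise_fst(ds, "wc")
        assert pw[0, 1] == pytest.approx(1.0)

    def test_duplicated_population_near_zero(self):
        """theta for a population paired with a copy of itself carries only
        the finite-sample correction term -(pq - h/4)/((n-1) pq), which
        shrinks like 1/n; it must be small and vanish with sample size."""
        rng = np.random.default_rng(11)
        thetas = {}
        for n in (25, 200):
            g = (rng.random((n, 40, 2)) < 0.4).astype(np.int16)
            dup = GenotypeDataset(genotypes=np.concatenate([g, g]),
                                  sample_pop=np.repeat([0, 1], n),
                                  pop_ids=["a", "a2"],
                                  locus_ids=[f"l{i}" for i in range(40)],
                                  kind="snp")
            thetas[n] = pairwise_fst(dup, "wc")[0, 1]
        assert abs(thetas[25]) < 1.0 / 25
        assert abs(thetas[200]) < 1.0 / 200
        assert abs(thetas[200]) < abs(thetas[25])

    @pytest.mark.parametrize("seed", range(15))
    def test_wc_matches_per_term_oracle(self, seed):
        ds = random_snp_dataset(seed + 100)
        pw = pairwise_fst(ds, "wc")
        for i in range(ds.n_pops):
            for j in range(i + 1, ds.n_pops):
                ref = oracle_wc_pair_theta(ds, i, j)
                if np.isfinite(ref):
                    assert pw[i, j] == pytest.approx(ref, abs=1e-10)

    def test_nei_method_symmetric_zero_diagonal(self):
        ds = random_microsat_dataset(4)
        pw = pairwise_fst(ds, "nei")
        assert np.allclose(pw, pw.T, equal_nan=True)
        assert np.allclose(np.diag(pw), 0)

    def test_roundtrip_identity_through_pooling(self):
        """Pooling a fully typed dataset leaves allele frequencies intact."""
        ds = random_snp_dataset(21, missing_prob=0.0)
        pool = pool_frequencies(ds)
        np.testing.assert_allclose(allele_frequencies(ds).freqs,
                                   allele_frequencies(pool).freqs, atol=1e-12)


class TestFisNanCorrelation:
    def test_constructed_perfect_negative(self):
        df = pd.DataFrame({"mean_fis": [-1.0, -2.0, -3.0, -4.0],
                           "mean_nan_fis": [1.0, 2.0, 3.0, 4.0]})
        r, p = fis_nan_correlation(df)
        assert r == pytest.approx(-1.0)

    def test_constant_nan_counts_undefined(self):
        df = pd.DataFrame({"mean_fis": [0.1, 0.2, 0.3],
                           "mean_nan_fis": [2.0, 2.0, 2.0]})
        r, p = fis_nan_correlation(df)
        assert np.isnan(r)

    def test_too_few_replicates(self):
        df = pd.DataFrame({"mean_fis": [0.1, 0.2], "mean_nan_fis": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fis_nan_correlation(df)
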