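"""Shared fixtures: seeded synthetic datasets at test scale.

The structured fixtures use a 16-deme model with low migration (exact
structured-coalescent path, visible population differentiation); the
ibd fixture plants true isolation by distance via distance-decayed
migration.  All are session-scoped: simulating them once keeps the
whole suite fast while every test still works on realistic data.
"""

import numpy as np
import pytest

from minsamp import (StatSuite, build_hierarchical_model, generate_landscape,
                     simulate_snp_genotypes)


@pytest.fixture(scope="session")
def structured():
    """16 demes x 12 diploids x 300 loci, island landscape, FST ~ 0.24."""
    model = build_hierarchical_model(regime="high", n_old=8, n_young=8,
                                     ne_old=800, m_within=5e-5, seed=1)
    meta, model = generate_landscape(model, mode="island", seed=7)
    ds = simulate_snp_genotypes(model, n_loci=300, n_diploids_per_pop=12,
                                seed=2)
    return ds, meta


@pytest.fixture(scope="session")
def ibd_dataset():
    """16 demes with distance-decayed migration: true IBD ground truth."""
    model = build_hierarchical_model(regime="high", n_old=8, n_young=8,
                                     ne_old=800, m_within=1e-4, seed=3)
    meta, model = generate_landscape(model, mode="ibd", seed=103,
                                     cluster_gap=0.0, scatter=3.0,
                                     env_noise=2.0, sigma_ibd=3.0)
    ds = simulate_snp_genotypes(model, n_loci=250, n_diploids_per_pop=10,
                                seed=203)
    return ds, meta


def random_snp_dataset(seed, max_pops=5, max_ind=6, max_loci=20,
                       missing_prob=0.1):
    """Small random SNP dataset for oracle-equivalence checks."""
    from minsamp import GenotypeDataset, MISSING

    rng = np.random.default_rng(seed)
    S = rng.integers(2, max_pops + 1)
    n_ind = rng.integers(2, max_ind + 1)
    L = rng.integers(2, max_loci + 1)
    p = rng.uniform(0.05, 0.95, size=(S, L))
    sample_pop = np.repeat(np.arange(S), n_ind)
    geno = (rng.random((S * n_ind, L, 2)) <
            p[sample_pop][:, :, None]).astype(np.int16)
    miss = rng.random((S * n_ind, L)) < missing_prob
    geno[miss] = MISSING
    return GenotypeDataset(genotypes=geno, sample_pop=sample_pop,
                           pop_ids=[f"p{i}" for i in range(S)],
                           locus_ids=[f"l{j}" for j in range(L)], kind="snp")


def random_microsat_dataset(seed, max_pops=4, max_ind=5, max_loci=8):
    from minsamp import GenotypeDataset, MISSING

    rng = np.random.default_rng(seed)
    S = rng.integers(2, max_pops + 1)
    n_ind = rng.integers(2, max_ind + 1)
    L = rng.integers(2, max_loci + 1)
    sample_pop = np.repeat(np.arange(S), n_ind)
    geno = rng.integers(8, 13, size=(S * n_ind, L, 2)).astype(np.int16)
    miss = rng.random((S * n_ind, L)) < 0.08
    geno[miss] = MISSING
    return GenotypeDataset(genotypes=geno, sample_pop=sample_pop,
                           pop_ids=[f"p{i}" for i in range(S)],
                           locus_ids=[f"l{j}" for j in range(L)],
                           kind="microsat")
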