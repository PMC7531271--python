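"""Synthetic data generation: hierarchical two-cluster demographies.

The generator emulates a population-genomic study system of 50 demes in
two genetic clusters: an "old" cluster of 25 demes (mean Ne 5,000) and a
"young" cluster of 25 demes (Ne smaller by a factor 1.5) that fuses into
the old cluster's first deme ``t_split`` (20,000) generations ago; the
old demes fuse into a single ancestral deme ``t_ancestral`` (140,000)
generations ago.  Migration is backward-in-time island-model gene flow
specified as a per-ordered-pair probability of a lineage moving between
two demes per generation: 0.001 within clusters, and either 0.0001
(high gene-flow regime) or 0 (low gene-flow regime) between clusters.
Per-deme parameters (Ne, migration, inbreeding F) are jittered with a
truncated normal so populations differ, as real populations do.

Loci are independent structured-coalescent genealogies (msprime), one
mutation each, placed uniformly at random along the branch length whose
derived-allele frequency in the pooled total sample falls inside the
ascertainment band ``[maf, 1 - maf]`` (SNP-array-like ascertainment;
with ``maf = 0`` every polymorphic site qualifies).  A genealogy without
qualifying branches is discarded and redrawn.

At the default within-cluster migration the per-pair scaled rate is
Nm ~ 10 (~240 immigrants per deme per generation), which places demes
deep in the panmictic limit of the island model: the probability that
two lineages in the same deme coalesce before either emigrates is
~0.002.  The generator therefore simulates each cluster as a single
panmictic pool of the summed deme sizes whenever min per-pair
within-cluster Nm >= ``COLLAPSE_NM`` (and no explicit migration matrix
is set), with deme labels indexing sampling blocks; this is orders of
magnitude faster and differs from the finite-migration model by less
than the Monte-Carlo noise of any statistic computed here.  Models with
low migration or an explicit (e.g. distance-decayed) migration matrix
are simulated with the full structured coalescent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import msprime
import numpy as np

from .datasets import GenotypeDataset, PoolFrequencyDataset, PopMetadata

#: Default regime means.
DEFAULTS = dict(
    n_old=25,
    n_young=25,
    ne_old=5000.0,
    ne_ratio=1.5,            # old Ne is 1.5x the young Ne
    m_within=0.001,          # per-pair within-cluster migration probability
    m_between_high=0.0001,   # per-pair between-cluster, high gene-flow regime
    t_split=20_000.0,        # generations, young demes fuse into the old cluster
    t_ancestral=140_000.0,   # generations, old demes fuse into one deme
    jitter_cv=0.10,
    f_sd=0.05,               # per-deme inbreeding F ~ max(N(0, f_sd), 0)
    maf=0.05,                # SNP ascertainment band
)

#: Minimum scaled total within-cluster emigration (2 Ne m (d-1)) for the
#: panmictic-limit collapse; at 50 the within-deme excess coancestry is
#: below ~1%.
COLLAPSE_NM = 50.0


@dataclass
class DemographicModel:
    """A fully specified two-cluster hierarchical island model.

    All per-deme arrays have length ``n_demes``; demes ``0..n_old-1``
    belong to the old cluster, the rest to the young cluster.
    ``m_within[i]``/``m_between[i]`` are the per-ordered-pair backward
    migration probabilities out of deme ``i`` towards each same-cluster /
    other-cluster deme.  An explicit ``migration_matrix`` (n x n, row =
    source deme backwards in time) overrides them.
    """

    n_old: int
    n_young: int
    ne: np.ndarray                  # diploid effective size per deme
    m_within: np.ndarray            # per-pair within-cluster rate, per deme
    m_between: np.ndarray           # per-pair between-cluster rate, per deme
    t_split: float
    t_ancestral: float
    f: np.ndarray                   # per-deme inbreeding coefficient
    regime: str = "high"
    seed: int | None = None
    jitter_cv: float = 0.10
    migration_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ne = np.asarray(self.ne, dtype=float)
        self.m_within = np.asarray(self.m_within, dtype=float)
        self.m_between = np.asarray(self.m_between, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        n = self.n_demes
        for name in ("ne", "m_within", "m_between", "f"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length n_demes={n}")
        if (self.ne <= 0).any():
            raise ValueError("all effective sizes must be positive")
        if ((self.m_within < 0) | (self.m_within > 1)).any() or \
           ((self.m_between < 0) | (self.m_between > 1)).any():
            raise ValueError("migration probabilities must lie in [0, 1]")
        if not (0 < self.t_split < self.t_ancestral):
            raise ValueError("need 0 < t_split < t_ancestral")
        if ((self.f < 0) | (self.f > 1)).any():
            raise ValueError("inbreeding coefficients must lie in [0, 1]")
        if self.migration_matrix is not None:
            self.migration_matrix = np.asarray(self.migration_matrix, dtype=float)
            if self.migration_matrix.shape != (n, n):
                raise ValueError("migration_matrix must be (n_demes, n_demes)")

    @property
    def n_demes(self) -> int:
        return self.n_old + self.n_young

    @property
    def cluster_of(self) -> np.ndarray:
        return np.array(["old"] * self.n_old + ["young"] * self.n_young)

    @property
    def deme_names(self) -> list[str]:
        return [f"old_{i}" for i in range(self.n_old)] + \
               [f"young_{i}" for i in range(self.n_young)]

    def pairwise_migration(self) -> np.ndarray:
        """The (n, n) backward migration-rate matrix actually simulated."""
        if self.migration_matrix is not None:
            return self.migration_matrix
        n = self.n_demes
        M = np.zeros((n, n))
        is_old = np.arange(n) < self.n_old
        for i in range(n):
            same = (is_old == is_old[i])
            same[i] = False
            M[i, same] = self.m_within[i]
            other = ~same & (np.arange(n) != i)
            if self.m_between[i] > 0:
                M[i, other] = self.m_between[i]
        return M

    def collapsible(self) -> bool:
        """True when within-cluster gene flow is strong enough that the
        panmictic-limit cluster collapse is numerically exact."""
        if self.migration_matrix is not None:
            return False
        if self.n_old < 2 or self.n_young < 2:
            return False
        n_same = np.where(np.arange(self.n_demes) < self.n_old,
                          self.n_old - 1, self.n_young - 1)
        nm_total = 2 * self.ne * self.m_within * n_same
        return bool(nm_total.min() >= COLLAPSE_NM)

    def to_msprime(self) -> msprime.Demography:
        """Full structured-coalescent demography (one population per deme)."""
        names = self.deme_names
        dem = msprime.Demography()
        dem.add_population(name=names[0], initial_size=self.ne[0],
                           initially_active=True)
        for i in range(1, self.n_demes):
            dem.add_population(name=names[i], initial_size=self.ne[i])
        M = self.pairwise_migration()
        for i in range(self.n_demes):
            for j in range(self.n_demes):
                if i != j and M[i, j] > 0:
                    dem.set_migration_rate(names[i], names[j], M[i, j])
        young = names[self.n_old:]
        if young:
            dem.add_population_split(time=self.t_split, derived=young,
                                     ancestral=names[0])
        if self.n_old > 1:
            dem.add_population_split(time=self.t_ancestral,
                                     derived=names[1:self.n_old],
                                     ancestral=names[0])
        dem.sort_events()
        return dem

    def to_msprime_collapsed(self) -> msprime.Demography:
        """Panmictic-limit demography: one pool per cluster."""
        dem = msprime.Demography()
        dem.add_population(name="OLD", initial_size=self.ne[:self.n_old].sum(),
                           initially_active=True)
        dem.add_population(name="YOUNG",
                           initial_size=self.ne[self.n_old:].sum())
        # per-lineage rate of moving to any deme of the other cluster
        mb_old = float(self.m_between[:self.n_old].mean()) * self.n_young
        mb_young = float(self.m_between[self.n_old:].mean()) * self.n_old
        if mb_old > 0:
            dem.set_migration_rate("OLD", "YOUNG", mb_old)
        if mb_young > 0:
            dem.set_migration_rate("YOUNG", "OLD", mb_young)
        dem.add_population_split(time=self.t_split, derived=["YOUNG"],
                                 ancestral="OLD")
        # after all demes have fused the ancestor is a single deme
        dem.add_population_parameters_change(time=self.t_ancestral,
                                             population="OLD",
                                             initial_size=self.ne[0])
        dem.sort_events()
        return dem

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        d = dict(d)
        for k in ("ne", "m_within", "m_between", "f"):
            d[k] = np.asarray(d[k], dtype=float)
        if d.get("migration_matrix") is not None:
            d["migration_matrix"] = np.asarray(d["migration_matrix"], dtype=float)
        return cls(**d)


def _truncated_normal(rng: np.random.Generator, mean, cv: float, size: int,
                      max_retries: int = 100) -> np.ndarray:
    """Jitter: normal around the mean, redrawn while non-positive
    (bounded retries), i.e. a truncation at zero."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,)).copy()
    if cv == 0:
        return mean
    out = rng.normal(mean, cv * mean)
    for _ in range(max_retries):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean[bad], cv * mean[bad])
    raise RuntimeError("could not draw positive demographic parameters")


def build_hierarchical_model(regime: str = "high",
                             n_old: int | None = None,
                             n_young: int | None = None,
                             ne_old: float | None = None,
                             ne_ratio: float | None = None,
                             m_within: float | None = None,
                             m_between: float | None = None,
                             t_split: float | None = None,
                             t_ancestral: float | None = None,
                             jitter_cv: float | None = None,
                             f_sd: float | None = None,
                             seed: int | None = None) -> DemographicModel:
    """Build a jittered two-cluster hierarchical island model.

    ``regime="high"`` uses a between-cluster per-pair migration
    probability one tenth of the within-cluster one (0.0001 at
    defaults); ``regime="low"`` shuts between-cluster gene flow off.
    Per-deme Ne and migration rates are truncated-normal draws with
    coefficient of variation ``jitter_cv`` around the regime means;
    split times are drawn once per model the same way; per-deme
    inbreeding is ``max(N(0, f_sd), 0)``.
    """
    if regime not in ("high", "low"):
        raise ValueError("regime must be 'high' or 'low'")
    D = DEFAULTS
    n_old = D["n_old"] if n_old is None else n_old
    n_young = D["n_young"] if n_young is None else n_young
    ne_old = D["ne_old"] if ne_old is None else ne_old
    ne_ratio = D["ne_ratio"] if ne_ratio is None else ne_ratio
    m_within = D["m_within"] if m_within is None else m_within
    if m_between is None:
        m_between = D["m_between_high"] if regime == "high" else 0.0
    t_split = D["t_split"] if t_split is None else t_split
    t_ancestral = D["t_ancestral"] if t_ancestral is None else t_ancestral
    jitter_cv = D["jitter_cv"] if jitter_cv is None else jitter_cv
    f_sd = D["f_sd"] if f_sd is None else f_sd
    if t_split < 0 or t_ancestral < 0:
        raise ValueError("split times must be positive")

    rng = np.random.default_rng(seed)
    n = n_old + n_young
    ne_mean = np.concatenate([np.full(n_old, ne_old),
                              np.full(n_young, ne_old / ne_ratio)])
    ne = _truncated_normal(rng, ne_mean, jitter_cv, n)
    mw = _truncated_normal(rng, m_within, jitter_cv, n)
    mb = _truncated_normal(rng, m_between, jitter_cv, n) if m_between > 0 \
        else np.zeros(n)
    ts_draw = float(_truncated_normal(rng, t_split, jitter_cv, 1)[0])
    ta_draw = float(_truncated_normal(rng, t_ancestral, jitter_cv, 1)[0])
    if ts_draw >= ta_draw:
        raise ValueError("drawn split times violate t_split < t_ancestral")
    f = np.maximum(rng.normal(0.0, f_sd, size=n), 0.0)
    return DemographicModel(n_old=n_old, n_young=n_young, ne=ne,
                            m_within=mw, m_between=mb,
                            t_split=ts_draw, t_ancestral=ta_draw,
                            f=f, regime=regime, seed=seed,
                            jitter_cv=jitter_cv)


# ---------------------------------------------------------------------------
# coalescent machinery


def _check_reachable(model: DemographicModel) -> None:
    if not np.isfinite(model.t_ancestral):
        raise ValueError("model has no reachable common ancestor")


def _setup_sim(model: DemographicModel, n_ind: int):
    """Demography + sample spec + node-layout helper for either path."""
    if model.collapsible():
        dem = model.to_msprime_collapsed()
        samples = {"OLD": model.n_old * n_ind, "YOUNG": model.n_young * n_ind}

        def layout(ts):
            old_nodes = ts.samples(population=0)
            young_nodes = ts.samples(population=1)
            nodes = np.concatenate([old_nodes, young_nodes])
            return nodes.reshape(model.n_demes, n_ind, 2)
    else:
        dem = model.to_msprime()
        samples = {name: n_ind for name in model.deme_names}

        def layout(ts):
            per_pop = [ts.samples(population=j) for j in range(model.n_demes)]
            return np.array(per_pop).reshape(model.n_demes, n_ind, 2)
    return dem, samples, layout


def _qualifying_branches(tree, maf: float):
    """Nodes whose subtended derived-allele frequency lies in the
    ascertainment band, with their branch lengths."""
    ts = tree.tree_sequence
    n = ts.num_samples
    parent = tree.parent_array
    nodes = np.array([u for u in tree.nodes() if parent[u] != -1])
    if nodes.size == 0:
        return nodes, np.empty(0)
    counts = np.array([tree.num_samples(u) for u in nodes])
    frac = counts / n
    lo = max(maf, 1e-12)
    qual = (frac >= lo) & (frac <= 1 - lo)
    qn = nodes[qual]
    lengths = np.array([tree.branch_length(u) for u in qn])
    return qn, lengths


def _one_mutation_haplotypes(tree, rng: np.random.Generator, maf: float,
                             length_cap: float) -> np.ndarray | None:
    """One ascertained mutation, with genealogies weighted by qualifying
    branch length; None when this genealogy is rejected.

    A segregating site falls on a given genealogy with probability
    proportional to the genealogy's branch length, so ascertained-SNP
    sampling must length-weight the trees, not take one site per tree.
    The tree is accepted with probability ``L_qual / length_cap`` (the
    cap is set from a pilot batch so that exceedance is negligible) and
    the mutation then placed length-uniformly on the qualifying set.
    """
    qn, lengths = _qualifying_branches(tree, maf)
    total = float(lengths.sum())
    if total <= 0:
        return None
    if rng.random() >= min(1.0, total / length_cap):
        return None
    u = qn[rng.choice(len(qn), p=lengths / total)]
    n = tree.tree_sequence.num_samples
    h = np.zeros(n, dtype=np.int16)
    h[list(tree.samples(u))] = 1
    return h


def _apply_inbreeding(geno: np.ndarray, sample_pop: np.ndarray,
                      f: np.ndarray, rng: np.random.Generator) -> None:
    """Locus-wise IBD copying: with probability F of the individual's
    deme, its second allele call becomes a copy of the first.  In place."""
    f_per_sample = f[sample_pop]
    ibd = rng.random(geno.shape[:2]) < f_per_sample[:, None]
    geno[:, :, 1] = np.where(ibd, geno[:, :, 0], geno[:, :, 1])


def simulate_snp_genotypes(model: DemographicModel, n_loci: int,
                           n_diploids_per_pop: int = 15,
                           seed: int | None = None,
                           maf: float | None = None,
                           batch_size: int = 512) -> GenotypeDataset:
    """Simulate ascertained biallelic SNP genotypes under the model.

    Each locus is one independent genealogy of all sampled haplotypes
    with one mutation on the ascertainment-qualifying branch set
    (length-weighted); genealogies without qualifying branches are
    redrawn.  Haplotypes are paired into diploids within demes and
    per-deme inbreeding F applied as locus-wise IBD copying.  ``maf``
    defaults to the package-wide ascertainment band (0.05).
    """
    if n_loci < 1 or n_diploids_per_pop < 1:
        raise ValueError("n_loci and n_diploids_per_pop must be >= 1")
    _check_reachable(model)
    maf = DEFAULTS["maf"] if maf is None else maf
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    dem, samples, layout = _setup_sim(model, n_diploids_per_pop)

    # pilot batch fixes the length cap for the length-weighted tree
    # acceptance (deterministic given the seed)
    pilot = msprime.sim_ancestry(samples=samples, demography=dem, ploidy=2,
                                 num_replicates=64,
                                 random_seed=int(rng.integers(1, 2**31 - 1)))
    pilot_lq = []
    for ts in pilot:
        _, lengths = _qualifying_branches(ts.first(), maf)
        pilot_lq.append(float(lengths.sum()))
    pilot_lq = np.array(pilot_lq)
    mean_lq = pilot_lq.mean() if pilot_lq.max() > 0 else 1.0
    cv = pilot_lq.std() / mean_lq if mean_lq > 0 else 1.0
    length_cap = max(mean_lq * (1.0 + 8.0 * cv), 1.5 * pilot_lq.max(), 1e-9)

    haps = []
    while len(haps) < n_loci:
        ms_seed = int(rng.integers(1, 2**31 - 1))
        todo = min(batch_size, max(32, 2 * (n_loci - len(haps))))
        reps = msprime.sim_ancestry(samples=samples, demography=dem,
                                    ploidy=2, num_replicates=todo,
                                    random_seed=ms_seed)
        for ts in reps:
            h = _one_mutation_haplotypes(ts.first(), rng, maf, length_cap)
            if h is not None:
                haps.append(h[layout(ts)])
            if len(haps) >= n_loci:
                break
    G = np.stack(haps, axis=2)                      # (deme, ind, loci, 2)
    n_ind = n_diploids_per_pop
    geno = G.reshape(model.n_demes * n_ind, n_loci, 2)
    sample_pop = np.repeat(np.arange(model.n_demes), n_ind)
    _apply_inbreeding(geno, sample_pop, model.f, rng)
    return GenotypeDataset(
        genotypes=geno, sample_pop=sample_pop,
        pop_ids=model.deme_names,
        locus_ids=[f"snp_{i + 1}" for i in range(n_loci)],
        kind="snp",
    )


def _stepwise_mutations(tree, rate: float, root_repeat: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Stepwise mutation model down one genealogy: Poisson(rate * branch
    length) mutations per branch, each +-1 repeat with equal probability.
    Returns per-sample repeat counts (floored at 1)."""
    ts = tree.tree_sequence
    values = np.zeros(ts.num_nodes, dtype=np.int64)
    parent = tree.parent_array
    for u in tree.preorder():
        p = parent[u]
        base = root_repeat if p == -1 else values[p]
        bl = 0.0 if p == -1 else tree.branch_length(u)
        k = rng.poisson(rate * bl) if bl > 0 else 0
        if k:
            steps = rng.integers(0, 2, size=k) * 2 - 1
            base = base + int(steps.sum())
        values[u] = base
    return np.maximum(values[ts.samples()], 1)


def simulate_microsat_genotypes(model: DemographicModel, n_loci: int = 22,
                                mutation_rate: float = 5e-4,
                                n_diploids_per_pop: int = 15,
                                seed: int | None = None,
                                root_repeat: int = 20) -> GenotypeDataset:
    """Simulate multi-allelic microsatellite genotypes (stepwise model).

    Same genealogies as the SNP mode; mutations are Poisson on branches
    with the given per-generation rate, each changing the repeat count
    by +-1 with equal probability from ``root_repeat`` at the root.  No
    ascertainment: a locus without mutations is monomorphic.
    """
    if mutation_rate < 0:
        raise ValueError("mutation_rate must be non-negative")
    _check_reachable(model)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    dem, samples, layout = _setup_sim(model, n_diploids_per_pop)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    reps = msprime.sim_ancestry(samples=samples, demography=dem,
                                ploidy=2, num_replicates=n_loci,
                                random_seed=ms_seed)
    haps = []
    for ts in reps:
        vals = _stepwise_mutations(ts.first(), mutation_rate, root_repeat, rng)
        haps.append(vals[layout(ts)])
    G = np.stack(haps, axis=2)
    n_ind = n_diploids_per_pop
    geno = G.reshape(model.n_demes * n_ind, n_loci, 2)
    sample_pop = np.repeat(np.arange(model.n_demes), n_ind)
    _apply_inbreeding(geno, sample_pop, model.f, rng)
    return GenotypeDataset(
        genotypes=geno, sample_pop=sample_pop,
        pop_ids=model.deme_names,
        locus_ids=[f"ms_{i + 1}" for i in range(n_loci)],
        kind="microsat",
    )


def pool_frequencies(ds: GenotypeDataset) -> PoolFrequencyDataset:
    """Pool a genotype dataset into per-population allele counts.

    Individual identity is discarded (downstream, Ho and FIS become
    unavailable, as for pooled-DNA sequencing data).  Individuals with a
    missing call at a locus are excluded from that locus's pool, so
    allele frequencies are unchanged by pooling.
    """
    from .stats import allele_frequencies  # local import to avoid cycle
    ft = allele_frequencies(ds)
    counts = np.nan_to_num(ft.freqs) * (2 * ft.n)[:, :, None]
    counts = np.rint(counts).astype(np.int64)
    return PoolFrequencyDataset(counts=counts, allele_values=ft.allele_values,
                                pop_ids=list(ds.pop_ids),
                                locus_ids=list(ds.locus_ids), kind=ds.kind)


# ---------------------------------------------------------------------------
# landscape generation


def generate_landscape(model: DemographicModel, mode: str = "island",
                       seed: int | None = None, n_env: int = 3,
                       cluster_gap: float = 10.0, scatter: float = 2.0,
                       env_noise: float = 0.3, sigma_ibd: float = 5.0,
                       sigma_cah: float = 8.0,
                       ) -> tuple[PopMetadata, DemographicModel]:
    """Planar coordinates and environmental covariates for the demes.

    Demes scatter around two cluster centres ``cluster_gap`` apart;
    environmental variables are linear spatial gradients plus Gaussian
    noise, so environment correlates with geography as bioclimatic
    variables do.

    ``mode="island"`` leaves the model untouched.  ``mode="ibd"``
    replaces migration by distance-decayed per-pair rates
    ``m_ij = m_within_i * exp(-d_ij / sigma_ibd)`` (true isolation by
    distance; as ``sigma_ibd -> inf`` this reduces to the uniform island
    rates).  ``mode="cah"`` rescales deme sizes to decrease strictly
    with distance from the coordinate centroid (true central-abundance
    structure).  Returns the metadata and the (possibly new) model.
    """
    if mode not in ("island", "ibd", "cah"):
        raise ValueError(f"unknown landscape mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = model.n_demes
    is_old = np.arange(n) < model.n_old
    centers = np.where(is_old[:, None],
                       np.array([[0.0, 0.0]]),
                       np.array([[cluster_gap, cluster_gap]]))
    coords = centers + rng.normal(0.0, scatter, size=(n, 2))
    grads = rng.normal(0.0, 1.0, size=(n_env, 2))
    env = coords @ grads.T + rng.normal(0.0, env_noise, size=(n, n_env))

    out_model = model
    if mode == "ibd":
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        M = model.m_within[:, None] * np.exp(-d / sigma_ibd)
        np.fill_diagonal(M, 0.0)
        out_model = dataclasses.replace(model, migration_matrix=M)
    elif mode == "cah":
        centroid = coords.mean(axis=0)
        d = np.linalg.norm(coords - centroid, axis=1)
        ne_ref = float(model.ne.mean())
        ne_new = ne_ref / (1.0 + d / sigma_cah)
        out_model = dataclasses.replace(model, ne=ne_new)

    meta = PopMetadata(pop_ids=model.deme_names, coords=coords, env=env,
                       planar=True)
    return meta, out_model
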