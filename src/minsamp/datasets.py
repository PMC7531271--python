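"""Core in-memory containers for genotype, pooled-frequency and landscape data.

The package works on three kinds of observation:

* individual diploid genotypes (SNP 0/1 codes or microsatellite repeat
  lengths) held in a :class:`GenotypeDataset`;
* per-population pooled allele counts (no individual identity, so
  observed heterozygosity and F_IS are not computable) held in a
  :class:`PoolFrequencyDataset`;
* per-population geographic coordinates and environmental covariates
  held in a :class:`PopMetadata` table.

Genotypes are stored as a dense ``(n_samples, n_loci, 2)`` integer array
with ``MISSING`` (= -1) for untyped allele calls, plus a population index
per sample.  This flat layout allows populations of unequal size, which
arises both in user-supplied data and after individual-axis subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Integer code for a missing allele call.
MISSING = -1


@dataclass
class GenotypeDataset:
    """Diploid genotypes for a set of populations.

    Parameters
    ----------
    genotypes
        Integer array of shape ``(n_samples, n_loci, 2)``.  For SNP data
        the allele codes are 0 (ancestral) and 1 (derived); for
        microsatellite data they are repeat counts.  ``MISSING`` marks an
        untyped call.
    sample_pop
        Array of shape ``(n_samples,)`` with the index into ``pop_ids``
        of each sample's population.
    pop_ids
        Population identifiers, one per population.
    locus_ids
        Locus identifiers, one per locus.
    sample_ids
        Per-sample identifiers; generated as ``"<pop>_<k>"`` if omitted.
    kind
        ``"snp"`` or ``"microsat"``; controls the writers and a few
        polymorphism checks.
    """

    genotypes: np.ndarray
    sample_pop: np.ndarray
    pop_ids: list[str]
    locus_ids: list[str]
    sample_ids: list[str] | None = None
    kind: str = "snp"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n_samples, n_loci, 2)")
        self.sample_pop = np.asarray(self.sample_pop, dtype=np.intp)
        if self.sample_pop.shape[0] != self.genotypes.shape[0]:
            raise ValueError("sample_pop length does not match genotypes")
        if self.kind not in ("snp", "microsat"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        counts = np.bincount(self.sample_pop, minlength=len(self.pop_ids))
        if (counts < 1).any():
            empty = [self.pop_ids[i] for i in np.flatnonzero(counts < 1)]
            raise ValueError(f"populations without individuals: {empty}")
        if self.sample_ids is None:
            k = np.zeros(len(self.pop_ids), dtype=int)
            ids = []
            for p in self.sample_pop:
                k[p] += 1
                ids.append(f"{self.pop_ids[p]}_{k[p]}")
            self.sample_ids = ids

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_pops(self) -> int:
        return len(self.pop_ids)

    def samples_of_pop(self, pop_index: int) -> np.ndarray:
        """Indices of the samples belonging to one population."""
        return np.flatnonzero(self.sample_pop == pop_index)

    def pop_sizes(self) -> np.ndarray:
        """Number of individuals per population."""
        return np.bincount(self.sample_pop, minlength=self.n_pops)

    def take_loci(self, locus_indices: np.ndarray) -> "GenotypeDataset":
        """New dataset restricted to the given loci (order preserved)."""
        locus_indices = np.asarray(locus_indices)
        return GenotypeDataset(
            genotypes=self.genotypes[:, locus_indices, :],
            sample_pop=self.sample_pop.copy(),
            pop_ids=list(self.pop_ids),
            locus_ids=[self.locus_ids[i] for i in locus_indices],
            sample_ids=list(self.sample_ids),
            kind=self.kind,
        )

    def take_pops(self, pop_indices: np.ndarray) -> "GenotypeDataset":
        """New dataset restricted to the given populations, reindexed."""
        pop_indices = np.asarray(pop_indices)
        keep = np.isin(self.sample_pop, pop_indices)
        remap = {int(old): new for new, old in enumerate(pop_indices)}
        new_sample_pop = np.array([remap[int(p)] for p in self.sample_pop[keep]])
        return GenotypeDataset(
            genotypes=self.genotypes[keep],
            sample_pop=new_sample_pop,
            pop_ids=[self.pop_ids[i] for i in pop_indices],
            locus_ids=list(self.locus_ids),
            sample_ids=[s for s, k in zip(self.sample_ids, keep) if k],
            kind=self.kind,
        )

    def take_samples(self, sample_indices: np.ndarray) -> "GenotypeDataset":
        """New dataset restricted to the given samples (all pops retained
        must still have at least one individual)."""
        sample_indices = np.asarray(sample_indices)
        sub_pop = self.sample_pop[sample_indices]
        kept_pops = np.unique(sub_pop)
        remap = {int(old): new for new, old in enumerate(kept_pops)}
        return GenotypeDataset(
            genotypes=self.genotypes[sample_indices],
            sample_pop=np.array([remap[int(p)] for p in sub_pop]),
            pop_ids=[self.pop_ids[i] for i in kept_pops],
            locus_ids=list(self.locus_ids),
            sample_ids=[self.sample_ids[i] for i in sample_indices],
            kind=self.kind,
        )


@dataclass
class PoolFrequencyDataset:
    """Per-population, per-locus allele counts (pooled data).

    ``counts[p, l, a]`` is the number of observed copies of allele
    ``allele_values[l, a]`` at locus ``l`` in population ``p``.  Padding
    slots carry allele value ``MISSING`` and count 0.
    """

    counts: np.ndarray
    allele_values: np.ndarray
    pop_ids: list[str]
    locus_ids: list[str]
    kind: str = "snp"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.allele_values = np.asarray(self.allele_values, dtype=np.int16)
        if self.counts.ndim != 3:
            raise ValueError("counts must have shape (n_pops, n_loci, n_alleles)")
        if self.allele_values.shape != self.counts.shape[1:]:
            raise ValueError("allele_values shape does not match counts")

    @property
    def n_pops(self) -> int:
        return len(self.pop_ids)

    @property
    def n_loci(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> np.ndarray:
        """Total observed allele copies per (pop, locus)."""
        return self.counts.sum(axis=2)

    def take_loci(self, locus_indices: np.ndarray) -> "PoolFrequencyDataset":
        locus_indices = np.asarray(locus_indices)
        return PoolFrequencyDataset(
            counts=self.counts[:, locus_indices, :],
            allele_values=self.allele_values[locus_indices],
            pop_ids=list(self.pop_ids),
            locus_ids=[self.locus_ids[i] for i in locus_indices],
            kind=self.kind,
        )

    def take_pops(self, pop_indices: np.ndarray) -> "PoolFrequencyDataset":
        pop_indices = np.asarray(pop_indices)
        return PoolFrequencyDataset(
            counts=self.counts[pop_indices],
            allele_values=self.allele_values.copy(),
            pop_ids=[self.pop_ids[i] for i in pop_indices],
            locus_ids=list(self.locus_ids),
            kind=self.kind,
        )


@dataclass
class PopMetadata:
    """Per-population coordinates and environmental covariates.

    ``coords`` are decimal-degree (lon, lat) unless ``planar`` is set, in
    which case they are Cartesian (synthetic landscapes use this).
    Derived columns (PC1 score, centroid distances) are filled in by the
    landscape routines and carried along so subsampling can reuse them.
    """

    pop_ids: list[str]
    coords: np.ndarray                      # (n_pops, 2) lon/lat or x/y
    env: np.ndarray                         # (n_pops, k) environmental variables
    planar: bool = False
    env_names: list[str] = field(default_factory=list)
    pc1: np.ndarray | None = None
    geo_centroid_dist: np.ndarray | None = None
    niche_centroid_dist: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.env = np.asarray(self.env, dtype=float)
        if self.coords.shape != (len(self.pop_ids), 2):
            raise ValueError("coords must have shape (n_pops, 2)")
        if self.env.shape[0] != len(self.pop_ids):
            raise ValueError("env must have one row per population")
        if len(set(self.pop_ids)) != len(self.pop_ids):
            raise ValueError("duplicated population ids in metadata")
        if not self.env_names:
            self.env_names = [f"env_{i + 1}" for i in range(self.env.shape[1])]

    @property
    def n_pops(self) -> int:
        return len(self.pop_ids)

    def take_pops(self, pop_indices: np.ndarray) -> "PopMetadata":
        pop_indices = np.asarray(pop_indices)

        def sub(a):
            return None if a is None else a[pop_indices]

        return PopMetadata(
            pop_ids=[self.pop_ids[i] for i in pop_indices],
            coords=self.coords[pop_indices],
            env=self.env[pop_indices],
            planar=self.planar,
            env_names=list(self.env_names),
            pc1=sub(self.pc1),
            geo_centroid_dist=sub(self.geo_centroid_dist),
            niche_centroid_dist=sub(self.niche_centroid_dist),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"pop_id": self.pop_ids,
                           "lon": self.coords[:, 0],
                           "lat": self.coords[:, 1]})
        for j, name in enumerate(self.env_names):
            df[name] = self.env[:, j]
        if self.pc1 is not None:
            df["pc1"] = self.pc1
        if self.geo_centroid_dist is not None:
            df["geo_centroid_dist"] = self.geo_centroid_dist
        if self.niche_centroid_dist is not None:
            df["niche_centroid_dist"] = self.niche_centroid_dist
        return df
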