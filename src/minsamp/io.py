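"""File formats: VCF and CSV genotype tables, pooled counts, metadata.

Conventions:

* SNP genotypes travel as biallelic VCF with GT fields; sample names
  follow ``"<pop>_<k>"`` so the population is the name up to the last
  underscore (an explicit sample-to-population mapping CSV overrides
  this).  Missing genotypes are ``./.``.
* Microsatellite genotypes travel as a CSV with columns ``pop``,
  ``ind`` and one column per locus holding ``"a1/a2"`` repeat pairs
  (``.`` for missing).
* Pooled data travel as a tidy CSV ``pop, locus, allele, count``.
* Population metadata is a CSV ``pop_id, lon, lat, env_*`` (+ optional
  ``planar`` handling for synthetic landscapes).

All writers round-trip: ``load(write(x)) == x``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset, PoolFrequencyDataset, PopMetadata


# ---------------------------------------------------------------------------
# VCF


def write_vcf(ds: GenotypeDataset, path: str) -> None:
    """Write SNP genotypes as a minimal biallelic VCF (GT only)."""
    if ds.kind != "snp":
        raise ValueError("VCF output is for SNP datasets")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.sample_ids) + "\n")
        G = ds.genotypes
        for l, lid in enumerate(ds.locus_ids):
            calls = []
            for s in range(ds.n_samples):
                a, b = G[s, l]
                if a < 0 or b < 0:
                    calls.append("./.")
                else:
                    calls.append(f"{a}/{b}")
            fh.write(f"1\t{l + 1}\t{lid}\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def _pop_from_sample_name(name: str) -> str:
    if "_" not in name:
        raise ValueError(f"sample {name!r} has no '<pop>_<k>' population prefix")
    return name.rsplit("_", 1)[0]


def load_vcf(path: str, pop_map: dict[str, str] | None = None,
             verbose: bool = False) -> GenotypeDataset:
    """Load biallelic SNP genotypes from a VCF.

    Multi-allelic records are skipped (their count is reported in the
    dataset's ``attrs`` analogue via a printed note when ``verbose``).
    Populations come from the sample-name prefix or ``pop_map``.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if pop_map is not None:
        unmapped = [s for s in samples if s not in pop_map]
        if unmapped:
            raise ValueError(f"samples without population mapping: {unmapped}")
        pops_per_sample = [pop_map[s] for s in samples]
    else:
        pops_per_sample = [_pop_from_sample_name(s) for s in samples]
    pop_ids: list[str] = []
    for p in pops_per_sample:
        if p not in pop_ids:
            pop_ids.append(p)
    sample_pop = np.array([pop_ids.index(p) for p in pops_per_sample])

    calls = []
    locus_ids = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        g = np.array([row[:2] for row in var.genotypes], dtype=np.int16)
        calls.append(g)
        locus_ids.append(var.ID if var.ID not in (None, ".")
                         else f"{var.CHROM}:{var.POS}")
    if n_skipped and verbose:
        print(f"skipped {n_skipped} multi-allelic record(s)")
    geno = np.stack(calls, axis=1) if calls else \
        np.empty((len(samples), 0, 2), dtype=np.int16)
    geno[geno < 0] = MISSING
    return GenotypeDataset(genotypes=geno, sample_pop=sample_pop,
                           pop_ids=pop_ids, locus_ids=locus_ids,
                           sample_ids=samples, kind="snp")


# ---------------------------------------------------------------------------
# microsatellite CSV


def write_microsat_csv(ds: GenotypeDataset, path: str) -> None:
    rows = []
    for s in range(ds.n_samples):
        row = {"pop": ds.pop_ids[ds.sample_pop[s]], "ind": ds.sample_ids[s]}
        for l, lid in enumerate(ds.locus_ids):
            a, b = ds.genotypes[s, l]
            row[lid] = "." if (a < 0 or b < 0) else f"{a}/{b}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_microsat_csv(path: str) -> GenotypeDataset:
    df = pd.read_csv(path, dtype=str)
    if not {"pop", "ind"}.issubset(df.columns):
        raise ValueError("microsatellite CSV needs 'pop' and 'ind' columns")
    loci = [c for c in df.columns if c not in ("pop", "ind")]
    pop_ids: list[str] = []
    for p in df["pop"]:
        if p not in pop_ids:
            pop_ids.append(p)
    sample_pop = np.array([pop_ids.index(p) for p in df["pop"]])
    geno = np.full((len(df), len(loci), 2), MISSING, dtype=np.int16)
    for l, lid in enumerate(loci):
        for s, cell in enumerate(df[lid]):
            if isinstance(cell, str) and cell != "." and cell != "":
                a, b = cell.split("/")
                geno[s, l] = (int(a), int(b))
    return GenotypeDataset(genotypes=geno, sample_pop=sample_pop,
                           pop_ids=pop_ids, locus_ids=loci,
                           sample_ids=list(df["ind"]), kind="microsat")


# ---------------------------------------------------------------------------
# pooled counts CSV


def write_pool_csv(ds: PoolFrequencyDataset, path: str) -> None:
    rows = []
    for p, pid in enumerate(ds.pop_ids):
        for l, lid in enumerate(ds.locus_ids):
            for a in range(ds.counts.shape[2]):
                av = ds.allele_values[l, a]
                if av == MISSING:
                    continue
                rows.append({"pop": pid, "locus": lid,
                             "allele": int(av), "count": int(ds.counts[p, l, a])})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_pool_csv(path: str, kind: str = "snp") -> PoolFrequencyDataset:
    df = pd.read_csv(path)
    need = {"pop", "locus", "allele", "count"}
    if not need.issubset(df.columns):
        raise ValueError(f"pooled CSV needs columns {sorted(need)}")
    pop_ids = list(dict.fromkeys(df["pop"].astype(str)))
    locus_ids = list(dict.fromkeys(df["locus"].astype(str)))
    allele_lists = [sorted(df.loc[df["locus"].astype(str) == lid, "allele"].unique())
                    for lid in locus_ids]
    A = max(len(a) for a in allele_lists)
    allele_values = np.full((len(locus_ids), A), MISSING, dtype=np.int16)
    counts = np.zeros((len(pop_ids), len(locus_ids), A), dtype=np.int64)
    for l, (lid, alleles) in enumerate(zip(locus_ids, allele_lists)):
        allele_values[l, :len(alleles)] = alleles
    pop_index = {p: i for i, p in enumerate(pop_ids)}
    locus_index = {l: i for i, l in enumerate(locus_ids)}
    for _, row in df.iterrows():
        p = pop_index[str(row["pop"])]
        l = locus_index[str(row["locus"])]
        a = list(allele_values[l]).index(row["allele"])
        counts[p, l, a] = row["count"]
    return PoolFrequencyDataset(counts=counts, allele_values=allele_values,
                                pop_ids=pop_ids, locus_ids=locus_ids, kind=kind)


# ---------------------------------------------------------------------------
# metadata CSV


def write_metadata_csv(meta: PopMetadata, path: str) -> None:
    df = meta.to_frame()
    df.insert(0, "planar", int(meta.planar))
    df.to_csv(path, index=False)


def load_metadata(path: str,
                  expected_pops: list[str] | None = None) -> PopMetadata:
    """Load and validate population metadata.

    With ``expected_pops`` the table must contain exactly those
    populations; offenders are named.  Non-numeric coordinates are
    rejected with their row number.
    """
    df = pd.read_csv(path)
    need = {"pop_id", "lon", "lat"}
    if not need.issubset(df.columns):
        raise ValueError(f"metadata CSV needs columns {sorted(need)}")
    ids = df["pop_id"].astype(str).tolist()
    dup = sorted({p for p in ids if ids.count(p) > 1})
    if dup:
        raise ValueError(f"duplicated population ids: {dup}")
    for col in ("lon", "lat"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        num = pd.to_numeric(df[col], errors="coerce")
        badrows = df.index[num.isna()].tolist()
        if badrows:
            raise ValueError(f"non-numeric {col} in row(s) {badrows}")
    if expected_pops is not None:
        extra = sorted(set(ids) - set(expected_pops))
        missing = sorted(set(expected_pops) - set(ids))
        if extra or missing:
            raise ValueError(
                f"metadata/population mismatch: extra={extra} missing={missing}")
    planar = bool(df["planar"].iloc[0]) if "planar" in df.columns else False
    derived = {"pc1", "geo_centroid_dist", "niche_centroid_dist", "planar"}
    env_cols = [c for c in df.columns
                if c not in need and c not in derived]
    meta = PopMetadata(
        pop_ids=ids,
        coords=df[["lon", "lat"]].to_numpy(dtype=float),
        env=df[env_cols].to_numpy(dtype=float) if env_cols
        else np.empty((len(ids), 0)),
        planar=planar, env_names=env_cols,
    )
    if "pc1" in df.columns:
        meta.pc1 = df["pc1"].to_numpy(dtype=float)
    if "geo_centroid_dist" in df.columns:
        meta.geo_centroid_dist = df["geo_centroid_dist"].to_numpy(dtype=float)
    if "niche_centroid_dist" in df.columns:
        meta.niche_centroid_dist = df["niche_centroid_dist"].to_numpy(dtype=float)
    return meta


def load_genotypes(path: str, fmt: str = "auto", pop_map_path: str | None = None):
    """Dispatching loader: ``vcf``, ``csv_genotypes`` or ``csv_pool``."""
    if fmt == "auto":
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "csv_genotypes"
    if fmt == "vcf":
        pop_map = None
        if pop_map_path:
            m = pd.read_csv(pop_map_path)
            pop_map = dict(zip(m.iloc[:, 0].astype(str), m.iloc[:, 1].astype(str)))
        return load_vcf(path, pop_map=pop_map)
    if fmt == "csv_genotypes":
        return load_microsat_csv(path)
    if fmt == "csv_pool":
        return load_pool_csv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_stats_csv(stats, path: str) -> None:
    """Tidy per-(locus, pop) statistics table: locus, pop, Ho, Hs, FIS."""
    rows = []
    for p, pid in enumerate(stats.pop_ids):
        for l, lid in enumerate(stats.locus_ids):
            rows.append({"locus": lid, "pop": pid,
                         "ho": stats.ho[p, l], "hs": stats.hs[p, l],
                         "fis": stats.fis[p, l]})
    pd.DataFrame(rows).to_csv(path, index=False)
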