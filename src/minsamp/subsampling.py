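"""Replicated subsampling designs and relative-error aggregation.

A :class:`SamplingDesign` names one axis — loci, individuals per
population, populations, or the individuals-vs-populations tradeoff —
and a level on that axis.  The engine redraws the subsample
``n_replicates`` times (without replacement within a replicate,
independently across replicates), recomputes the full statistic suite
on every subsample, and summarises the replicate distribution against
the full-data reference with the relative error
``(X_est - X_sim) / X_est`` (positive = the subsample underestimates).

Replicate ``i`` derives its seed deterministically from the design seed
(``SeedSequence(design_seed).spawn``-style keying), so any single
replicate can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import GenotypeDataset, PoolFrequencyDataset, PopMetadata
from . import stats as mstats
from . import landscape as mland

AXES = ("loci", "individuals", "populations", "tradeoff")

#: Statistics treated as associations for sign-flip accounting.
ASSOCIATION_STATS = ("mrm_beta_geo", "mrm_beta_env", "cah_geo_slope",
                     "cah_niche_slope")


@dataclass
class SamplingDesign:
    """One subsampling axis, level and replication setting."""

    axis: str
    level: int | tuple[int, int]
    n_replicates: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}; one of {AXES}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.axis == "tradeoff":
            ind, pops = self.level
            if ind < 1 or pops < 1:
                raise ValueError("tradeoff level must be (individuals, populations)")
        elif int(self.level) < 1:
            raise ValueError("level must be >= 1")


@dataclass
class StatSuite:
    """Which statistics to compute per (sub)dataset."""

    basic: bool = True
    landscape: bool = False
    mrm_permutations: int = 0         # 0: report coefficients only
    fst_method: str | None = None     # None: "wc" for SNPs, "nei" for microsats
    n_niche_pcs: int = 2


def replicate_seed(design_seed: int | None, i: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed derived from the design seed."""
    return np.random.SeedSequence(0 if design_seed is None else design_seed,
                                  spawn_key=(i,))


def draw_subsample(dataset, metadata: PopMetadata | None,
                   design: SamplingDesign,
                   rep_seed) -> tuple[object, PopMetadata | None]:
    """One uniform without-replacement subsample along the design axis.

    ``rep_seed`` is the per-replicate seed (int or SeedSequence).  The
    populations and tradeoff axes subset the metadata consistently; the
    individuals axis requires genotype (not pooled) data and samples
    independently within each population.
    """
    rng = np.random.default_rng(rep_seed)
    pooled = isinstance(dataset, PoolFrequencyDataset)

    def sample_individuals(ds: GenotypeDataset, k: int) -> GenotypeDataset:
        sizes = ds.pop_sizes()
        if (sizes < k).any():
            small = [ds.pop_ids[i] for i in np.flatnonzero(sizes < k)]
            raise ValueError(f"populations with fewer than {k} individuals: {small}")
        picked = []
        for p in range(ds.n_pops):
            idx = ds.samples_of_pop(p)
            picked.append(rng.choice(idx, size=k, replace=False))
        return ds.take_samples(np.sort(np.concatenate(picked)))

    if design.axis == "loci":
        k = int(design.level)
        if k > dataset.n_loci:
            raise ValueError(f"requested {k} of {dataset.n_loci} loci")
        loci = np.sort(rng.choice(dataset.n_loci, size=k, replace=False))
        return dataset.take_loci(loci), metadata

    if design.axis == "individuals":
        if pooled:
            raise ValueError("individuals axis needs genotype data, not pooled")
        return sample_individuals(dataset, int(design.level)), metadata

    if design.axis == "populations":
        k = int(design.level)
        if k > dataset.n_pops:
            raise ValueError(f"requested {k} of {dataset.n_pops} populations")
        pops = np.sort(rng.choice(dataset.n_pops, size=k, replace=False))
        meta = metadata.take_pops(pops) if metadata is not None else None
        return dataset.take_pops(pops), meta

    # tradeoff: joint (individuals per pop, populations)
    if pooled:
        raise ValueError("tradeoff axis needs genotype data, not pooled")
    n_ind, n_pops = design.level
    if n_pops > dataset.n_pops:
        raise ValueError(f"requested {n_pops} of {dataset.n_pops} populations")
    pops = np.sort(rng.choice(dataset.n_pops, size=int(n_pops), replace=False))
    meta = metadata.take_pops(pops) if metadata is not None else None
    sub = dataset.take_pops(pops)
    return sample_individuals(sub, int(n_ind)), meta


def relative_error(x_est: float, x_sim: float) -> float:
    """``(x_est - x_sim) / x_est``; NaN when the reference is 0 or not finite.

    Overestimates give negative error."""
    if not np.isfinite(x_est) or x_est == 0 or not np.isfinite(x_sim):
        return float("nan")
    return (x_est - x_sim) / x_est


def compute_suite(dataset, metadata: PopMetadata | None,
                  suite: StatSuite, seed=None) -> dict[str, float]:
    """The statistic suite on one dataset: summary statistics and
    (optionally) the landscape associations."""
    out: dict[str, float] = {}
    if suite.basic:
        st = mstats.basic_stats(dataset)
        out["mean_hs"] = st.mean_hs
        out["mean_ho"] = st.mean_ho
        out["mean_fis"] = st.mean_fis
        out["fst"] = st.fst_overall
        if st.has_genotypes:
            out["mean_nan_fis"] = float(np.mean(st.nan_fis_count))
        else:
            out["mean_nan_fis"] = float("nan")
    if suite.landscape:
        if metadata is None:
            raise ValueError("landscape statistics need population metadata")
        method = suite.fst_method or \
            ("nei" if getattr(dataset, "kind", "snp") == "microsat" else "wc")
        fst_mat = mstats.pairwise_fst(dataset, method=method)
        meta = mland.centroid_distances(metadata, n_niche_pcs=suite.n_niche_pcs)
        dm = mland.distance_matrices(meta, fst_mat)
        if suite.mrm_permutations > 0:
            mr = mland.mrm(dm.genetic, dm.geographic, dm.environmental,
                           n_permutations=suite.mrm_permutations, seed=seed)
            out["mrm_p_geo"] = mr.p_geo
            out["mrm_p_env"] = mr.p_env
        else:
            mr = mland.mrm_fit_only(dm.genetic, dm.geographic, dm.environmental)
        out["mrm_beta_geo"] = mr.beta_geo
        out["mrm_beta_env"] = mr.beta_env
        out["mrm_r2"] = mr.r_squared
        if "mean_hs" not in out:
            out["mean_hs"] = mstats.basic_stats(dataset).mean_hs
        hs_pop = mstats.basic_stats(dataset).pop_mean_hs
        cg = mland.cah_regression(hs_pop, meta.geo_centroid_dist, "geographic")
        cn = mland.cah_regression(hs_pop, meta.niche_centroid_dist, "niche")
        out["cah_geo_slope"] = cg.slope
        out["cah_niche_slope"] = cn.slope
    return out


def run_design(dataset, metadata: PopMetadata | None,
               design: SamplingDesign,
               suite: StatSuite | None = None) -> pd.DataFrame:
    """Replicate table: one row per replicate with the full suite.

    Per-replicate statistic failures (e.g. undefined FST in a degenerate
    subsample) are recorded as NaN cells, never aborting the run.
    """
    suite = suite or StatSuite()
    rows = []
    for i in range(design.n_replicates):
        ss = replicate_seed(design.seed, i)
        sub, meta = draw_subsample(dataset, metadata, design, ss)
        row: dict[str, object] = {"replicate": i}
        try:
            row.update(compute_suite(sub, meta, suite,
                                     seed=np.random.default_rng(ss)))
        except ValueError:
            pass                                        # leave cells undefined
        row["unit_ids"] = _unit_ids(sub, design)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["axis"] = design.axis
    df.attrs["level"] = design.level
    df.attrs["seed"] = design.seed
    return df


def _unit_ids(sub, design: SamplingDesign) -> str:
    if design.axis == "loci":
        ids = sub.locus_ids
        if len(ids) > 50:
            return f"{len(ids)} loci"
        return ";".join(ids)
    if design.axis == "populations":
        return ";".join(sub.pop_ids)
    ids = getattr(sub, "sample_ids", None) or []
    if len(ids) > 50:
        return f"{len(ids)} individuals"
    return ";".join(ids)


def summarize_replicates(table: pd.DataFrame,
                         reference: dict[str, float]) -> pd.DataFrame:
    """Distribution summaries and relative errors per statistic.

    Two relative errors are reported (the mean of per-replicate errors
    and the error of the replicate mean); for association statistics the
    sign-flip proportion is the fraction of replicates whose coefficient
    has the opposite sign to the reference.
    """
    stats_cols = [c for c in table.columns
                  if c not in ("replicate", "unit_ids") and c in reference]
    missing = [c for c in table.columns
               if c not in ("replicate", "unit_ids") and c not in reference]
    if missing:
        raise ValueError(f"statistics absent from the reference: {missing}")
    rows = []
    for c in stats_cols:
        x = pd.to_numeric(table[c], errors="coerce").to_numpy(dtype=float)
        ref = reference[c]
        good = np.isfinite(x)
        n_undef = int((~good).sum())
        xg = x[good]
        row = {
            "statistic": c,
            "reference": ref,
            "n_replicates": len(x),
            "n_undefined": n_undef,
            "mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan,
            "q025": np.nan, "q25": np.nan, "median": np.nan,
            "q75": np.nan, "q975": np.nan,
            "rel_error_of_mean": np.nan, "mean_rel_error": np.nan,
            "sign_flip": np.nan,
        }
        if xg.size:
            q = np.quantile(xg, [0.025, 0.25, 0.5, 0.75, 0.975])
            row.update(mean=xg.mean(), sd=xg.std(ddof=1) if xg.size > 1 else 0.0,
                       min=xg.min(), max=xg.max(),
                       q025=q[0], q25=q[1], median=q[2], q75=q[3], q975=q[4])
            row["rel_error_of_mean"] = relative_error(ref, float(xg.mean()))
            per_rep = np.array([relative_error(ref, v) for v in xg])
            if np.isfinite(per_rep).any():
                row["mean_rel_error"] = float(np.nanmean(per_rep))
            if c in ASSOCIATION_STATS and np.isfinite(ref) and ref != 0:
                row["sign_flip"] = float(np.mean(np.sign(xg) == -np.sign(ref)))
        rows.append(row)
    return pd.DataFrame(rows)
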