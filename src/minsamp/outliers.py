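"""Outlier-SNP detection and the population-count detection experiment.

The detector is a fully specified two-stage genome scan:

1. *Differentiation test.*  For each locus, a parametric null
   distribution of the locus-specific Weir & Cockerham theta is built by
   drawing population allele frequencies from the Balding-Nichols beta
   distribution ``Beta(pbar (1-theta)/theta, (1-pbar)(1-theta)/theta)``
   at the observed pooled frequency ``pbar`` and genome-wide theta, then
   binomial allele counts at the observed per-population sample sizes.
   The p-value is the upper-tail proportion of null thetas at or above
   the observed one (observed counted).

2. *Environmental-association test.*  The per-locus statistic is the
   absolute Pearson correlation between population allele frequencies
   and the environmental PC1 score; the null permutes the environment
   vector over populations (the same permutations reused across loci).

Both p-value sets are converted to q-values by Benjamini-Hochberg, and a
locus is flagged as an outlier when *both* q-values fall below the
threshold (default 0.05) — differentiation alone is not enough, the
locus must also be environment-associated.

The population-count experiment repeats the scan over designs that
subsample 5, 10, 20, 30 ... populations, recording the maximum locus
FST, outlier counts and cross-replicate outlier-set intersections, the
quantities through which reduced population sampling inflates apparent
differentiation and erodes detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import GenotypeDataset, PoolFrequencyDataset, PopMetadata
from . import stats as mstats
from .landscape import env_pc1


@dataclass
class OutlierResult:
    locus_ids: list[str]
    locus_fst: np.ndarray
    global_fst: float
    max_fst: float
    diff_p: np.ndarray
    diff_q: np.ndarray
    assoc_p: np.ndarray
    assoc_q: np.ndarray
    flags: np.ndarray
    q_threshold: float
    status: str = "ok"              # "skipped" when global theta <= 0

    @property
    def n_outliers(self) -> int:
        return int(self.flags.sum())

    def outlier_ids(self) -> list[str]:
        return [l for l, f in zip(self.locus_ids, self.flags) if f]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus": self.locus_ids, "fst": self.locus_fst,
            "diff_p": self.diff_p, "diff_q": self.diff_q,
            "assoc_p": self.assoc_p, "assoc_q": self.assoc_q,
            "outlier": self.flags,
        })


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH q-values (monotone step-up); NaN p-values stay NaN."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    good = np.isfinite(p)
    pg = p[good]
    m = pg.size
    if m == 0:
        return q
    order = np.argsort(pg, kind="mergesort")
    ranked = pg[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qg = np.empty(m)
    qg[order] = np.minimum(ranked, 1.0)
    q[good] = qg
    return q


def locus_fst_scan(ds: GenotypeDataset | PoolFrequencyDataset,
                   ft: mstats.FreqTable | None = None):
    """Per-locus Weir & Cockerham theta and the multilocus global theta.

    Monomorphic-in-sample loci have undefined theta (NaN) and are
    excluded from any maximum taken downstream.
    """
    if ds.n_pops < 2:
        raise ValueError("FST scan requires at least 2 populations")
    num, den = mstats.wc_theta_components(ds, ft=ft)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = num / den
    per_locus[~np.isfinite(per_locus)] = np.nan
    ok = np.isfinite(num) & np.isfinite(den)
    global_theta = float(num[ok].sum() / den[ok].sum()) if ok.any() else float("nan")
    return per_locus, global_theta


def _pooled_freq_and_sizes(ds, ft: mstats.FreqTable):
    """Derived-allele pooled frequency (loci,) and per-pop haploid sizes."""
    n_hap = 2 * ft.n                                    # (pops, loci)
    p = ft.freqs[:, :, -1] if ds.kind == "snp" else ft.freqs[:, :, -1]
    with np.errstate(invalid="ignore"):
        pbar = np.nansum(n_hap * p, axis=0) / n_hap.sum(axis=0)
    return p, pbar, n_hap


def fst_outlier_test(ds: GenotypeDataset | PoolFrequencyDataset,
                     n_null: int = 10_000, seed: int | None = None,
                     chunk: int = 64):
    """Differentiation p and BH q per locus from the beta-binomial null.

    Null locus thetas are computed with the same count-based estimator
    as the observed per-locus statistic, at the observed per-population
    haploid sample sizes.  Returns ``(p, q, status)``; when the
    genome-wide theta is not in (0, 1) the test is skipped and all
    p-values are NaN with ``status="skipped"``.
    """
    if ds.kind != "snp":
        raise ValueError("the outlier scan is defined for biallelic SNP data")
    ft = mstats.allele_frequencies(ds)
    n_hap = (2 * ft.n)                                  # (S, L)
    p_obs = ft.freqs[:, :, -1]
    L = ds.n_loci
    # count-based theta, observed, per locus (consistent with the null)
    obs_num, obs_den = _pooled_theta_components(n_hap, p_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_obs = obs_num / obs_den
    ok = np.isfinite(obs_num) & np.isfinite(obs_den)
    theta_hat = float(obs_num[ok].sum() / obs_den[ok].sum()) if ok.any() else np.nan
    if not (0 < theta_hat < 1):
        return np.full(L, np.nan), np.full(L, np.nan), "skipped"

    with np.errstate(invalid="ignore"):
        pbar = np.nansum(n_hap * p_obs, axis=0) / n_hap.sum(axis=0)
    # loci monomorphic (or untyped) in the current population subset have
    # no defined locus-specific differentiation: left out of the test
    testable = np.isfinite(theta_obs) & (pbar > 0) & (pbar < 1)
    idx = np.flatnonzero(testable)
    Lt = idx.size
    p = np.full(L, np.nan)
    if Lt == 0:
        return p, benjamini_hochberg(p), "ok"
    a_shape = pbar[idx] * (1 - theta_hat) / theta_hat
    b_shape = (1 - pbar[idx]) * (1 - theta_hat) / theta_hat
    rng = np.random.default_rng(seed)
    count_ge = np.ones(Lt)                              # observed counted
    S = ds.n_pops
    sizes = np.nan_to_num(n_hap[:, idx]).astype(int)    # (S, Lt)
    theta_ref = theta_obs[idx]
    for k0 in range(0, n_null, chunk):
        k = min(chunk, n_null - k0)
        # (k, S, Lt) population frequencies from the Balding-Nichols prior
        pf = rng.beta(np.broadcast_to(a_shape, (k, S, Lt)),
                      np.broadcast_to(b_shape, (k, S, Lt)))
        counts = rng.binomial(np.broadcast_to(sizes, (k, S, Lt)), pf)
        with np.errstate(invalid="ignore", divide="ignore"):
            phat = counts / sizes
        num, den = _pooled_theta_components(
            np.broadcast_to(sizes, (k, S, Lt)).astype(float), phat, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta_null = num / den
        count_ge += np.nansum(theta_null >= theta_ref[None, :], axis=0)
    p[idx] = count_ge / (n_null + 1)
    return p, benjamini_hochberg(p), "ok"


def _pooled_theta_components(n_hap, p, axis: int = 0):
    """Haploid-ANOVA theta components over populations (along ``axis``)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = n_hap > 0
        r = valid.sum(axis=axis)
        ntot = np.where(valid, n_hap, 0).sum(axis=axis)
        n2 = np.where(valid, n_hap ** 2, 0).sum(axis=axis)
        nc = (ntot - n2 / ntot) / (r - 1)
        w = np.where(valid, n_hap, 0)
        pw = np.where(valid, p, 0)
        pbar = (w * pw).sum(axis=axis) / ntot
        pbar_e = np.expand_dims(pbar, axis)
        msp = (w * (np.where(valid, p, pbar_e) - pbar_e) ** 2).sum(axis=axis) / (r - 1)
        msg = (w * pw * (1 - pw)).sum(axis=axis) / (ntot - r)
        num = msp - msg
        den = msp + (nc - 1) * msg
        bad = (r < 2) | (ntot <= r)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def env_association_test(ds: GenotypeDataset | PoolFrequencyDataset,
                         env: np.ndarray, n_permutations: int = 1000,
                         seed: int | None = None):
    """Per-locus environment association p and BH q.

    Statistic: |Pearson r| between population derived-allele frequency
    and the environmental value; null from permutations of the
    environment vector over populations, shared across loci; upper-tail
    p with the observed configuration counted.
    """
    env = np.asarray(env, dtype=float)
    if env.shape[0] != ds.n_pops:
        raise ValueError("env must have one value per population")
    if np.std(env) == 0:
        raise ValueError("constant environmental vector")
    ft = mstats.allele_frequencies(ds)
    freq = ft.freqs[:, :, -1]                           # (S, L)
    obs = _abs_corr(freq, env)
    rng = np.random.default_rng(seed)
    count = np.ones(freq.shape[1])
    for _ in range(n_permutations - 1):
        perm = rng.permutation(len(env))
        count += _abs_corr(freq, env[perm]) >= obs
    p = count / n_permutations
    p[~np.isfinite(obs)] = np.nan
    return p, benjamini_hochberg(p)


def _abs_corr(freq: np.ndarray, env: np.ndarray) -> np.ndarray:
    """|Pearson r| between each locus's frequencies (rows of pops) and env,
    NaN-aware per locus."""
    f = freq
    good = np.isfinite(f)
    n = good.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(good, env[:, None], np.nan)
        fm = np.nanmean(f, axis=0)
        em = np.nanmean(e, axis=0)
        fc = np.where(good, f - fm, 0)
        ec = np.where(good, e - em, 0)
        cov = (fc * ec).sum(axis=0)
        denom = np.sqrt((fc ** 2).sum(axis=0) * (ec ** 2).sum(axis=0))
        r = np.abs(cov / denom)
    r[n < 3] = np.nan
    return r


def detect_outliers(ds, env: np.ndarray, q_threshold: float = 0.05,
                    n_null: int = 10_000, n_permutations: int = 1000,
                    seed: int | None = None) -> OutlierResult:
    """Joint scan: a locus is an outlier when both the differentiation
    and the environment-association q-values fall below the threshold."""
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    locus_fst, global_fst = locus_fst_scan(ds)
    diff_p, diff_q, status = fst_outlier_test(ds, n_null=n_null, seed=s1)
    assoc_p, assoc_q = env_association_test(ds, env,
                                            n_permutations=n_permutations,
                                            seed=s2)
    with np.errstate(invalid="ignore"):
        flags = (diff_q < q_threshold) & (assoc_q < q_threshold)
    flags = np.where(np.isnan(diff_q) | np.isnan(assoc_q), False, flags)
    finite = locus_fst[np.isfinite(locus_fst)]
    return OutlierResult(
        locus_ids=list(ds.locus_ids), locus_fst=locus_fst,
        global_fst=global_fst,
        max_fst=float(finite.max()) if finite.size else float("nan"),
        diff_p=diff_p, diff_q=diff_q, assoc_p=assoc_p, assoc_q=assoc_q,
        flags=flags.astype(bool), q_threshold=q_threshold, status=status)


def plant_env_clines(ds: GenotypeDataset, env: np.ndarray, n_planted: int,
                     seed: int | None = None, steepness: float = 2.0,
                     missing_prob: float = 0.0) -> tuple[GenotypeDataset, list[str]]:
    """Plant environment-associated loci by deforming allele frequencies
    toward a logistic cline in the environment (synthetic ground truth).

    The last ``n_planted`` loci are replaced: population target derived
    frequencies follow ``1 / (1 + exp(-steepness * z))`` with ``z`` the
    standardised environment, and genotypes are redrawn binomially per
    individual.  Returns the new dataset and the planted locus ids.
    """
    env = np.asarray(env, dtype=float)
    z = (env - env.mean()) / env.std()
    target = 1.0 / (1.0 + np.exp(-steepness * z))       # (S,)
    rng = np.random.default_rng(seed)
    geno = ds.genotypes.copy()
    L = ds.n_loci
    planted_idx = np.arange(L - n_planted, L)
    for l in planted_idx:
        p_ind = target[ds.sample_pop]
        draws = rng.random((ds.n_samples, 2)) < p_ind[:, None]
        geno[:, l, :] = draws.astype(np.int16)
    ids = [ds.locus_ids[i] for i in planted_idx]
    out = GenotypeDataset(genotypes=geno, sample_pop=ds.sample_pop.copy(),
                          pop_ids=list(ds.pop_ids), locus_ids=list(ds.locus_ids),
                          sample_ids=list(ds.sample_ids), kind=ds.kind)
    return out, ids


def population_count_experiment(ds: GenotypeDataset, meta: PopMetadata,
                                levels=(5, 10, 20, 30, None),
                                reps: int = 10, n_loci: int | None = 10_000,
                                q_threshold: float = 0.05,
                                n_null: int = 10_000,
                                n_permutations: int = 1000,
                                seed: int | None = None) -> pd.DataFrame:
    """The population-count detection experiment.

    A single locus subsample of ``n_loci`` is drawn once and shared by
    every level and replicate.  For each level (None = all populations)
    and replicate, populations are drawn without replacement, the joint
    outlier scan run, and the maximum locus FST, outlier count and
    outlier ids recorded.  The returned table carries one row per
    (level, replicate); per-level all-replicate intersection counts and
    the across-everything intersection are in ``df.attrs``.
    """
    ss = np.random.SeedSequence(seed)
    s_loci, s_levels = ss.spawn(2)
    if n_loci is not None and n_loci < ds.n_loci:
        rng = np.random.default_rng(s_loci)
        loci = np.sort(rng.choice(ds.n_loci, size=n_loci, replace=False))
        ds = ds.take_loci(loci)
    env_scores = meta.pc1 if meta.pc1 is not None else env_pc1(meta.env)
    rows = []
    sets: dict[object, list[set]] = {}
    for li, level in enumerate(levels):
        k = ds.n_pops if level is None else int(level)
        if k > ds.n_pops:
            raise ValueError(f"level {k} exceeds {ds.n_pops} populations")
        for rep in range(reps):
            rs = np.random.SeedSequence(
                0 if seed is None else seed, spawn_key=(1, li, rep))
            rng = np.random.default_rng(rs)
            pops = np.sort(rng.choice(ds.n_pops, size=k, replace=False))
            sub = ds.take_pops(pops)
            res = detect_outliers(sub, env_scores[pops],
                                  q_threshold=q_threshold, n_null=n_null,
                                  n_permutations=n_permutations,
                                  seed=int(rng.integers(2**31 - 1)))
            ids = set(res.outlier_ids())
            sets.setdefault(level, []).append(ids)
            rows.append({
                "level": "all" if level is None else level,
                "n_pops": k, "replicate": rep,
                "pop_ids": ";".join(sub.pop_ids),
                "max_fst": res.max_fst, "global_fst": res.global_fst,
                "n_outliers": res.n_outliers,
                "outlier_ids": ";".join(sorted(ids)),
                "status": res.status,
            })
    df = pd.DataFrame(rows)
    inter_per_level = {}
    all_sets = []
    for level, ls in sets.items():
        inter = set.intersection(*ls) if ls else set()
        inter_per_level["all" if level is None else level] = len(inter)
        all_sets.extend(ls)
    df.attrs["intersection_per_level"] = inter_per_level
    df.attrs["intersection_all"] = len(set.intersection(*all_sets)) if all_sets else 0
    return df
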