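"""Population-genetic summary statistics with explicit NaN semantics.

Implements the classical gene-diversity estimators:

* per (locus, population): observed heterozygosity ``Ho``, Nei's
  sample-size-corrected gene diversity
  ``Hs = n/(n-1) * (1 - sum_a p_a^2 - Ho/(2n))``, and the inbreeding
  coefficient ``FIS = 1 - Ho/Hs`` (undefined where ``Hs = 0``);
* per locus overall: the Nei/Chesser-corrected total diversity
  ``Ht = 1 - sum_a pbar_a^2 + Hsbar/(nh*s) - Hobar/(2*nh*s)`` with
  ``nh`` the harmonic-mean sample size over the ``s`` populations, and
  ``FST = (Ht - Hsbar)/Ht``;
* pairwise Weir & Cockerham (1984) theta, multilocus ratio-of-sums.

Undefined cells (``FIS`` at loci fixed within a population, statistics at
(locus, population) cells without typed individuals) are carried as NaN
and *counted*, never silently dropped: the per-population NaN counts are
themselves an object of study, because subsampling individuals turns
low-frequency alleles into within-population fixation and the resulting
NaNs bias the mean ``FIS`` downward.

Negative ``FST`` values, which arise from the sample-size corrections in
weakly differentiated data, are reported as computed and never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .datasets import MISSING, GenotypeDataset, PoolFrequencyDataset


@dataclass
class FreqTable:
    """Per-locus per-population allele frequencies and sample sizes.

    ``freqs[p, l, a]`` is the frequency of allele ``allele_values[l, a]``
    in population ``p`` at locus ``l`` (NaN where no typed individuals);
    ``n[p, l]`` is the number of typed individuals (pooled data: half the
    observed allele copies, so the downstream corrections see an
    individual-equivalent count).
    """

    freqs: np.ndarray
    n: np.ndarray
    allele_values: np.ndarray
    pop_ids: list[str]
    locus_ids: list[str]
    from_pool: bool = False


@dataclass
class SummaryStats:
    """The full summary-statistic suite for one dataset.

    Per-cell arrays have shape ``(n_pops, n_loci)``.  ``ho``/``fis`` are
    all-NaN for pooled input, and ``has_genotypes`` is False there.
    Grand means weight populations equally.
    """

    pop_ids: list[str]
    locus_ids: list[str]
    ho: np.ndarray
    hs: np.ndarray
    fis: np.ndarray
    nan_fis_count: np.ndarray        # per pop, number of undefined FIS cells
    pop_mean_ho: np.ndarray
    pop_mean_hs: np.ndarray
    pop_mean_fis: np.ndarray
    ht: np.ndarray                   # per locus
    fst_per_locus: np.ndarray
    fst_overall: float               # ratio-of-sums across loci
    fst_mean_of_ratios: float
    mean_ho: float
    mean_hs: float
    mean_fis: float
    has_genotypes: bool


# ---------------------------------------------------------------------------
# allele frequencies


def _genotype_freq_table(ds: GenotypeDataset) -> FreqTable:
    G = ds.genotypes
    typed = (G >= 0).all(axis=2)                       # (samples, loci)
    if ds.kind == "snp":
        allele_values = np.tile(np.array([0, 1], dtype=np.int16), (ds.n_loci, 1))
        A = 2
    else:
        vals = np.unique(G[G >= 0])
        per_locus = []
        for l in range(ds.n_loci):
            g = G[:, l, :]
            per_locus.append(np.unique(g[g >= 0]))
        A = max((len(v) for v in per_locus), default=1)
        A = max(A, 1)
        allele_values = np.full((ds.n_loci, A), MISSING, dtype=np.int16)
        for l, v in enumerate(per_locus):
            allele_values[l, : len(v)] = v
    n = np.zeros((ds.n_pops, ds.n_loci))
    freqs = np.full((ds.n_pops, ds.n_loci, A), np.nan)
    for p in range(ds.n_pops):
        idx = ds.samples_of_pop(p)
        t = typed[idx]                                  # (ind, loci)
        n[p] = t.sum(axis=0)
        g = G[idx]                                      # (ind, loci, 2)
        if ds.kind == "snp":
            ones = np.where(t[:, :, None], g, 0).sum(axis=(0, 2))
            with np.errstate(invalid="ignore", divide="ignore"):
                p1 = ones / (2 * n[p])
            freqs[p, :, 0] = 1 - p1
            freqs[p, :, 1] = p1
        else:
            for l in range(ds.n_loci):
                av = allele_values[l]
                gl = g[:, l, :][t[:, l]]
                if gl.size == 0:
                    continue
                counts = (gl.ravel()[:, None] == av[None, :]).sum(axis=0)
                freqs[p, l] = counts / gl.size
    return FreqTable(freqs=freqs, n=n, allele_values=allele_values,
                     pop_ids=list(ds.pop_ids), locus_ids=list(ds.locus_ids))


def _pool_freq_table(ds: PoolFrequencyDataset) -> FreqTable:
    totals = ds.totals().astype(float)                  # allele copies
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = ds.counts / totals[:, :, None]
    freqs[totals == 0] = np.nan
    return FreqTable(freqs=freqs, n=totals / 2.0,
                     allele_values=ds.allele_values,
                     pop_ids=list(ds.pop_ids), locus_ids=list(ds.locus_ids),
                     from_pool=True)


def allele_frequencies(ds: GenotypeDataset | PoolFrequencyDataset) -> FreqTable:
    """Per-(locus, population) allele frequencies, excluding missing calls.

    An individual is counted as typed at a locus only if both allele
    calls are present.
    """
    if isinstance(ds, GenotypeDataset):
        return _genotype_freq_table(ds)
    return _pool_freq_table(ds)


def observed_heterozygosity(ds: GenotypeDataset) -> np.ndarray:
    """Ho per (pop, locus): heterozygote proportion among typed individuals."""
    G = ds.genotypes
    typed = (G >= 0).all(axis=2)
    het = typed & (G[:, :, 0] != G[:, :, 1])
    ho = np.full((ds.n_pops, ds.n_loci), np.nan)
    for p in range(ds.n_pops):
        idx = ds.samples_of_pop(p)
        nt = typed[idx].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho[p] = het[idx].sum(axis=0) / nt
    return ho


# ---------------------------------------------------------------------------
# basic statistics


def basic_stats(ds: GenotypeDataset | PoolFrequencyDataset,
                freq_table: FreqTable | None = None) -> SummaryStats:
    """Compute the Ho/Hs/FIS/Ht/FST suite for one dataset.

    Pooled input has no individual genotypes: Ho and FIS are emitted as
    all-NaN with ``has_genotypes=False`` (an explicit "unavailable"
    marker), ``Hs = n/(n-1)(1 - sum p^2)`` with n half the pool count,
    and Ht omits the Ho terms.

    The overall FST is reported both as the ratio of per-locus sums
    (default, ``fst_overall``) and as the mean of per-locus ratios.
    """
    ft = freq_table if freq_table is not None else allele_frequencies(ds)
    has_geno = isinstance(ds, GenotypeDataset)
    if not has_geno and ds.n_pops < 2:
        raise ValueError("FST requires at least 2 populations")
    n = ft.n                                            # (pops, loci) individuals
    sum_p2 = np.nansum(ft.freqs ** 2, axis=2)
    sum_p2[np.isnan(ft.freqs).all(axis=2)] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        if has_geno:
            ho = observed_heterozygosity(ds)
            hs = n / (n - 1) * (1 - sum_p2 - ho / (2 * n))
        else:
            ho = np.full_like(sum_p2, np.nan)
            hs = n / (n - 1) * (1 - sum_p2)
        hs[n <= 1] = np.nan
        # numerical guard: fixation can produce tiny negative values
        hs[np.abs(hs) < 1e-15] = 0.0
        fis = 1 - ho / hs
        fis[~np.isfinite(fis)] = np.nan
        if not has_geno:
            fis[:] = np.nan

    # a FIS cell is "NaN" when the locus has data for the population but the
    # statistic is undefined (fixation: Hs = 0; or no typed individuals)
    if has_geno:
        nan_fis = np.isnan(fis).sum(axis=1)
    else:
        nan_fis = np.full(len(ft.pop_ids), -1)          # unavailable

    # per-locus totals over populations with data
    present = ~np.isnan(hs)                             # (pops, loci)
    s = present.sum(axis=0).astype(float)               # pops per locus
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = np.where(present[:, :, None], np.nan_to_num(ft.freqs), 0.0
                        ).sum(axis=0) / np.where(s > 0, s, np.nan)[:, None]
        sum_pbar2 = np.nansum(pbar ** 2, axis=1)
        nh = s / np.nansum(np.where(present, 1.0 / n, np.nan), axis=0)
        hs_bar = np.where(s > 0, np.where(present, hs, 0).sum(axis=0), np.nan) / s
        ht = 1 - sum_pbar2 + hs_bar / (nh * s)
        if has_geno:
            ho_bar = np.where(s > 0, np.where(present, ho, 0).sum(axis=0),
                              np.nan) / s
            ht = ht - ho_bar / (2 * nh * s)
        ht[s < 2] = np.nan
        fst_per_locus = (ht - hs_bar) / ht
        fst_per_locus[~np.isfinite(fst_per_locus)] = np.nan

    ok = ~np.isnan(ht) & ~np.isnan(hs_bar) & (ht != 0)
    if ok.any() and np.nansum(ht[ok]) != 0:
        fst_overall = float((ht[ok] - hs_bar[ok]).sum() / ht[ok].sum())
    else:
        fst_overall = float("nan")
    fst_mor = float(np.nanmean(fst_per_locus)) if np.isfinite(fst_per_locus).any() else float("nan")

    with np.errstate(invalid="ignore"):
        pop_mean_ho = np.nanmean(ho, axis=1) if has_geno else np.full(len(ft.pop_ids), np.nan)
        pop_mean_hs = np.nanmean(hs, axis=1)
        pop_mean_fis = _nanmean_or_nan_rows(fis)

    return SummaryStats(
        pop_ids=list(ft.pop_ids), locus_ids=list(ft.locus_ids),
        ho=ho, hs=hs, fis=fis, nan_fis_count=nan_fis,
        pop_mean_ho=pop_mean_ho, pop_mean_hs=pop_mean_hs,
        pop_mean_fis=pop_mean_fis,
        ht=ht, fst_per_locus=fst_per_locus,
        fst_overall=fst_overall, fst_mean_of_ratios=fst_mor,
        mean_ho=_safe_mean(pop_mean_ho) if has_geno else float("nan"),
        mean_hs=_safe_mean(pop_mean_hs),
        mean_fis=_safe_mean(pop_mean_fis) if has_geno else float("nan"),
        has_genotypes=has_geno,
    )


def _safe_mean(a: np.ndarray) -> float:
    good = np.isfinite(a)
    return float(a[good].mean()) if good.any() else float("nan")


def _nanmean_or_nan_rows(a: np.ndarray) -> np.ndarray:
    out = np.full(a.shape[0], np.nan)
    for i in range(a.shape[0]):
        row = a[i]
        good = ~np.isnan(row)
        if good.any():
            out[i] = row[good].mean()
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham theta


def pop_moments(ds: GenotypeDataset, ft: FreqTable | None = None):
    """Per-population W&C ingredients: typed counts n (S, L), allele
    frequencies p (S, L, A) and per-allele heterozygote frequencies
    h (S, L, A)."""
    if ft is None:
        ft = allele_frequencies(ds)
    G = ds.genotypes
    typed = (G >= 0).all(axis=2)
    S, L, A = ds.n_pops, ds.n_loci, ft.freqs.shape[2]
    h = np.zeros((S, L, A))
    for p in range(S):
        idx = ds.samples_of_pop(p)
        g = G[idx]
        t = typed[idx]
        het = t & (g[:, :, 0] != g[:, :, 1])
        nt = t.sum(axis=0).astype(float)
        for a in range(A):
            av = ft.allele_values[:, a][None, :]        # (1, loci)
            carries = het & ((g[:, :, 0] == av) | (g[:, :, 1] == av))
            with np.errstate(invalid="ignore", divide="ignore"):
                h[p, :, a] = carries.sum(axis=0) / nt
    return ft.n, ft.freqs, h


def _wc_components_genotype(ds: GenotypeDataset, pop_indices: np.ndarray,
                            ft: FreqTable | None = None):
    """Per-locus W&C (1984) a and b+c sums over alleles for the given pops."""
    n, freqs, h = pop_moments(ds, ft)
    sub = np.asarray(pop_indices)
    return _wc_from_moments(n[sub], freqs[sub], h[sub])


def _wc_from_moments(n: np.ndarray, freqs: np.ndarray, h: np.ndarray | None):
    """W&C 1984 components from per-pop sizes/frequencies (+het freqs).

    ``n``: (r, loci) individuals; ``freqs``: (r, loci, A); ``h``: same
    shape as freqs or None for pooled data (heterozygosity terms then
    follow the haploid-style estimator with h = 0 and sizes doubled is
    *not* used -- see pairwise_fst docstring).
    """
    r_eff = (n > 0).sum(axis=0).astype(float)           # pops with data, per locus
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = np.where(r_eff > 0, n.sum(axis=0) / r_eff, np.nan)
        nc = (r_eff * nbar - (n ** 2).sum(axis=0) / (r_eff * nbar)) / (r_eff - 1)
        w = n[:, :, None]
        pbar = np.nansum(w * freqs, axis=0) / (r_eff * nbar)[:, None]
        s2 = np.nansum(w * (freqs - pbar[None]) ** 2, axis=0) / ((r_eff - 1) * nbar)[:, None]
        if h is not None:
            hbar = np.nansum(w * h, axis=0) / (r_eff * nbar)[:, None]
        else:
            hbar = np.zeros_like(pbar)
        pq = pbar * (1 - pbar)
        frac = (r_eff - 1)[:, None] / r_eff[:, None]
        a = (nbar[:, None] / nc[:, None]) * (
            s2 - (1.0 / (nbar[:, None] - 1)) * (pq - frac * s2 - hbar / 4))
        b = (nbar[:, None] / (nbar[:, None] - 1)) * (
            pq - frac * s2 - ((2 * nbar[:, None] - 1) / (4 * nbar[:, None])) * hbar)
        c = hbar / 2
    a_sum = np.nansum(a, axis=1)
    bc_sum = np.nansum(b, axis=1) + np.nansum(c, axis=1)
    bad = (r_eff < 2) | ~np.isfinite(nbar) | (nbar <= 1)
    a_sum[bad] = np.nan
    bc_sum[bad] = np.nan
    return a_sum, bc_sum


def wc_theta_components(ds: GenotypeDataset | PoolFrequencyDataset,
                        pop_indices: np.ndarray | None = None,
                        ft: FreqTable | None = None):
    """Per-locus numerator (a) and denominator (a+b+c) W&C components.

    Pooled data carry no heterozygosity information; allele copies are
    treated as haploid observations (the moment estimator on allele
    counts, i.e. the same ANOVA with within-individual terms absent).
    """
    if pop_indices is None:
        pop_indices = np.arange(ds.n_pops)
    if isinstance(ds, GenotypeDataset):
        a, bc = _wc_components_genotype(ds, pop_indices, ft)
        return a, a + bc
    # pooled: haploid ANOVA on allele copies
    ftp = ft if ft is not None else allele_frequencies(ds)
    sub = np.asarray(pop_indices)
    ncop = (2 * ftp.n[sub])                             # allele copies (r, loci)
    freqs = ftp.freqs[sub]
    r_eff = (ncop > 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ntot = ncop.sum(axis=0)
        nc = (ntot - (ncop ** 2).sum(axis=0) / ntot) / (r_eff - 1)
        w = ncop[:, :, None]
        pbar = np.nansum(w * freqs, axis=0) / ntot[:, None]
        msp = np.nansum(w * (freqs - pbar[None]) ** 2, axis=0) / (r_eff - 1)[:, None]
        msg = np.nansum(w * freqs * (1 - freqs), axis=0) / (ntot - r_eff)[:, None]
        num = (msp - msg)
        den = msp + (nc[:, None] - 1) * msg
    a_sum = np.nansum(num, axis=1)
    d_sum = np.nansum(den, axis=1)
    bad = (r_eff < 2) | (ntot <= r_eff)
    a_sum[bad] = np.nan
    d_sum[bad] = np.nan
    return a_sum, d_sum


def pairwise_fst(ds: GenotypeDataset | PoolFrequencyDataset,
                 method: str = "wc") -> np.ndarray:
    """Pairwise FST matrix between populations.

    ``method="wc"``: Weir & Cockerham (1984) theta for each pair,
    multilocus ratio-of-sums.  Genotype input uses the full a/b/c
    decomposition with heterozygosity terms; pooled input uses the
    analogous haploid ANOVA estimator on allele counts.

    ``method="nei"``: the Nei/Chesser-corrected ``(Ht - Hsbar)/Ht`` of
    :func:`basic_stats`, restricted to the pair, ratio-of-sums over loci
    (the convention used for microsatellite data).

    The matrix is symmetric with zero diagonal; a pair with no co-typed
    loci yields NaN.
    """
    if ds.n_pops < 2:
        raise ValueError("pairwise FST requires at least 2 populations")
    S = ds.n_pops
    out = np.zeros((S, S))
    ft = allele_frequencies(ds)
    if method == "wc":
        I, J = np.triu_indices(S, k=1)
        if isinstance(ds, GenotypeDataset):
            n, freqs, h = pop_moments(ds, ft)
        else:
            n, freqs, h = 2 * ft.n, ft.freqs, None
        theta = np.empty(len(I))
        chunk = max(1, int(2e6 // max(ds.n_loci, 1)))   # bound memory use
        for k0 in range(0, len(I), chunk):
            sl = slice(k0, k0 + chunk)
            i, j = I[sl], J[sl]
            if h is not None:
                theta[sl] = _wc_pairs_genotype(n[i], freqs[i], h[i],
                                               n[j], freqs[j], h[j])
            else:
                theta[sl] = _wc_pairs_pooled(n[i], freqs[i], n[j], freqs[j])
        out[I, J] = theta
        out[J, I] = theta
    elif method == "nei":
        for i in range(S):
            for j in range(i + 1, S):
                sub = _take_pops_any(ds, np.array([i, j]))
                st = basic_stats(sub)
                out[i, j] = out[j, i] = st.fst_overall
    else:
        raise ValueError(f"unknown pairwise FST method {method!r}")
    return out


def _take_pops_any(ds, pop_indices):
    return ds.take_pops(pop_indices)


def _wc_pairs_genotype(nI, pI, hI, nJ, pJ, hJ) -> np.ndarray:
    """Multilocus W&C theta for many population pairs at once.

    Inputs have shape (P, L) / (P, L, A); returns theta per pair as the
    ratio of summed a-components to summed a+b+c over loci and alleles.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = (nI > 0) & (nJ > 0)
        nbar = (nI + nJ) / 2.0
        valid &= nbar > 1
        nc = nI * nJ / nbar
        w_sum = (2 * nbar)[:, :, None]
        pbar = (nI[:, :, None] * pI + nJ[:, :, None] * pJ) / w_sum
        s2 = (nI[:, :, None] * (pI - pbar) ** 2
              + nJ[:, :, None] * (pJ - pbar) ** 2) / nbar[:, :, None]
        hbar = (nI[:, :, None] * hI + nJ[:, :, None] * hJ) / w_sum
        pq = pbar * (1 - pbar)
        nb = nbar[:, :, None]
        a = (nbar / nc)[:, :, None] * (
            s2 - (pq - s2 / 2 - hbar / 4) / (nb - 1))
        b = nb / (nb - 1) * (pq - s2 / 2 - (2 * nb - 1) / (4 * nb) * hbar)
        c = hbar / 2
        num = np.where(valid[:, :, None], a, np.nan).sum(axis=2)
        den = np.where(valid[:, :, None], a + b + c, np.nan).sum(axis=2)
        num_s = np.nansum(np.where(valid, num, np.nan), axis=1)
        den_s = np.nansum(np.where(valid, den, np.nan), axis=1)
        theta = num_s / den_s
    theta[~valid.any(axis=1)] = np.nan
    return theta


def _wc_pairs_pooled(ncI, pI, ncJ, pJ) -> np.ndarray:
    """Multilocus haploid-ANOVA theta for many pairs (pooled counts)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = (ncI > 0) & (ncJ > 0) & (ncI + ncJ > 2)
        ntot = ncI + ncJ
        nc = 2 * ncI * ncJ / ntot
        pbar = (ncI[:, :, None] * pI + ncJ[:, :, None] * pJ) / ntot[:, :, None]
        msp = (ncI[:, :, None] * (pI - pbar) ** 2
               + ncJ[:, :, None] * (pJ - pbar) ** 2)
        msg = (ncI[:, :, None] * pI * (1 - pI)
               + ncJ[:, :, None] * pJ * (1 - pJ)) / (ntot - 2)[:, :, None]
        num = np.where(valid[:, :, None], msp - msg, np.nan).sum(axis=2)
        den = np.where(valid[:, :, None],
                       msp + (nc[:, :, None] - 1) * msg, np.nan).sum(axis=2)
        theta = np.nansum(np.where(valid, num, np.nan), axis=1) / \
            np.nansum(np.where(valid, den, np.nan), axis=1)
    theta[~valid.any(axis=1)] = np.nan
    return theta


# ---------------------------------------------------------------------------
# FIS / NaN diagnostics


def fis_nan_correlation(replicate_table) -> tuple[float, float]:
    """Pearson correlation between per-replicate mean FIS and mean NaN count.

    ``replicate_table`` is the DataFrame produced by the subsampling
    engine for an individuals-axis design; it must contain ``mean_fis``
    and ``mean_nan_fis`` columns.  Returns ``(r, p)``; ``(nan, nan)``
    when either column is constant (the correlation is then undefined).
    """
    df = replicate_table
    x = np.asarray(df["mean_fis"], dtype=float)
    y = np.asarray(df["mean_nan_fis"], dtype=float)
    good = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[good], y[good]
    if len(x) < 3:
        raise ValueError("need at least 3 replicates for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
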