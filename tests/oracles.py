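"""Naive per-term reference implementations used as independent oracles.

Everything here is written with explicit Python loops straight from the
textbook formulas (Nei's corrected gene diversities; the Weir &
Cockerham 1984 analysis-of-variance components), deliberately sharing no
code with the package's vectorised estimators.
"""

import math

import numpy as np


def oracle_basic_stats(ds):
    """Ho/Hs/FIS per (pop, locus), Ht/FST per locus, overall ratio-of-sums.

    Returns a dict of plain nested lists/floats; NaN where undefined.
    """
    S, L = ds.n_pops, ds.n_loci
    G = ds.genotypes
    ho = [[math.nan] * L for _ in range(S)]
    hs = [[math.nan] * L for _ in range(S)]
    fis = [[math.nan] * L for _ in range(S)]
    freqs = [[None] * L for _ in range(S)]
    ns = [[0] * L for _ in range(S)]
    for p in range(S):
        idx = [i for i in range(ds.n_samples) if ds.sample_pop[i] == p]
        for l in range(L):
            typed = [i for i in idx if G[i, l, 0] >= 0 and G[i, l, 1] >= 0]
            n = len(typed)
            ns[p][l] = n
            if n == 0:
                continue
            alleles = {}
            n_het = 0
            for i in typed:
                a, b = int(G[i, l, 0]), int(G[i, l, 1])
                alleles[a] = alleles.get(a, 0) + 1
                alleles[b] = alleles.get(b, 0) + 1
                if a != b:
                    n_het += 1
            freq = {a: c / (2 * n) for a, c in alleles.items()}
            freqs[p][l] = freq
            ho[p][l] = n_het / n
            if n > 1:
                sum_p2 = sum(f ** 2 for f in freq.values())
                hs[p][l] = n / (n - 1) * (1 - sum_p2 - ho[p][l] / (2 * n))
                if abs(hs[p][l]) < 1e-15:
                    hs[p][l] = 0.0
                if hs[p][l] != 0:
                    fis[p][l] = 1 - ho[p][l] / hs[p][l]
    ht = [math.nan] * L
    fst = [math.nan] * L
    for l in range(L):
        pops = [p for p in range(S) if ns[p][l] > 1 and not math.isnan(hs[p][l])]
        s = len(pops)
        if s < 2:
            continue
        all_alleles = set()
        for p in pops:
            all_alleles |= set(freqs[p][l])
        pbar = {a: sum(freqs[p][l].get(a, 0.0) for p in pops) / s
                for a in all_alleles}
        nh = s / sum(1.0 / ns[p][l] for p in pops)
        hs_bar = sum(hs[p][l] for p in pops) / s
        ho_bar = sum(ho[p][l] for p in pops) / s
        ht[l] = (1 - sum(v ** 2 for v in pbar.values())
                 + hs_bar / (nh * s) - ho_bar / (2 * nh * s))
        if ht[l] != 0:
            fst[l] = (ht[l] - hs_bar) / ht[l]
    num = sum((ht[l] - (sum(hs[p][l] for p in range(S)
                            if ns[p][l] > 1 and not math.isnan(hs[p][l]))
                        / max(1, len([p for p in range(S)
                                      if ns[p][l] > 1 and not math.isnan(hs[p][l])]))))
              for l in range(L) if not math.isnan(ht[l]))
    den = sum(ht[l] for l in range(L) if not math.isnan(ht[l]))
    overall = num / den if den else math.nan
    return {"ho": ho, "hs": hs, "fis": fis, "ht": ht, "fst_per_locus": fst,
            "fst_overall": overall}


def oracle_wc_pair_theta(ds, i, j):
    """Multilocus W&C (1984) theta for one population pair, per-term.

    Per-allele a, b, c components with r = 2, ratio of sums over loci."""
    G = ds.genotypes
    sum_a = 0.0
    sum_abc = 0.0
    for l in range(ds.n_loci):
        data = {}
        for p in (i, j):
            idx = [k for k in range(ds.n_samples) if ds.sample_pop[k] == p]
            typed = [k for k in idx if G[k, l, 0] >= 0 and G[k, l, 1] >= 0]
            if len(typed) == 0:
                data = None
                break
            counts = {}
            hets = {}
            for k in typed:
                a, b = int(G[k, l, 0]), int(G[k, l, 1])
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
                if a != b:
                    hets[a] = hets.get(a, 0) + 1
                    hets[b] = hets.get(b, 0) + 1
            n = len(typed)
            data[p] = (n, {a: c / (2 * n) for a, c in counts.items()},
                       {a: hets.get(a, 0) / n for a in counts})
        if data is None:
            continue
        n1, p1, h1 = data[i]
        n2, p2, h2 = data[j]
        nbar = (n1 + n2) / 2
        if nbar <= 1:
            continue
        r = 2
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        for a in set(p1) | set(p2):
            pa1, pa2 = p1.get(a, 0.0), p2.get(a, 0.0)
            ha1, ha2 = h1.get(a, 0.0), h2.get(a, 0.0)
            pbar = (n1 * pa1 + n2 * pa2) / (r * nbar)
            s2 = (n1 * (pa1 - pbar) ** 2 + n2 * (pa2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * ha1 + n2 * ha2) / (r * nbar)
            a_comp = (nbar / nc) * (s2 - 1 / (nbar - 1)
                                    * (pbar * (1 - pbar)
                                       - ((r - 1) / r) * s2 - hbar / 4))
            b_comp = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                            - ((r - 1) / r) * s2
                                            - ((2 * nbar - 1) / (4 * nbar)) * hbar)
            c_comp = hbar / 2
            sum_a += a_comp
            sum_abc += a_comp + b_comp + c_comp
    return sum_a / sum_abc if sum_abc else math.nan


def oracle_wc_theta_counts(n_hap, p):
    """Haploid-ANOVA theta from allele counts for one biallelic locus.

    ``n_hap``: list of haploid sample sizes; ``p``: derived frequencies."""
    pops = [(n, f) for n, f in zip(n_hap, p) if n > 0]
    r = len(pops)
    ntot = sum(n for n, _ in pops)
    if r < 2 or ntot <= r:
        return math.nan
    nc = (ntot - sum(n ** 2 for n, _ in pops) / ntot) / (r - 1)
    pbar = sum(n * f for n, f in pops) / ntot
    msp = sum(n * (f - pbar) ** 2 for n, f in pops) / (r - 1)
    msg = sum(n * f * (1 - f) for n, f in pops) / (ntot - r)
    den = msp + (nc - 1) * msg
    return (msp - msg) / den if den else math.nan
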