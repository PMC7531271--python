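"""Replicated subsampling designs over loci, individuals and populations.

Runs the replicated-design grid on one simulated dataset (default the
high-flow model from 01_simulate.py): loci at 100 / 1,000 / a near-half
subset, individuals at 3 / 6 / 9 per population, populations at
5 / 10 / 20 / 30 / 40, and the individuals-vs-populations tradeoff
(3 ind x 49 pops, 6 x 24, 9 x 10 — capped at what the dataset holds).
Replicate counts default to 200 (the distributions are already stable;
pass --replicates 1000 for the full design).

Writes per-design replicate tables and a combined summary with relative
errors and sign-flip proportions under results/designs/.
"""

import argparse
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from minsamp import (SamplingDesign, StatSuite, compute_suite, run_design,
                     summarize_replicates)
from minsamp.io import load_genotypes, load_metadata


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--genotypes", default="results/data/sim_high.vcf")
    ap.add_argument("--metadata", default="results/data/sim_high_metadata.csv")
    ap.add_argument("--replicates", type=int, default=200)
    ap.add_argument("--seed", type=int, default=2)
    ap.add_argument("--out-dir", default="results/designs")
    args = ap.parse_args()
    os.makedirs(args.out_dir, exist_ok=True)

    ds = load_genotypes(args.genotypes)
    meta = load_metadata(args.metadata, ds.pop_ids)
    suite = StatSuite(landscape=True)
    ref = compute_suite(ds, meta, suite)
    print("reference:", {k: round(v, 4) for k, v in ref.items()})

    n_ind_min = int(ds.pop_sizes().min())
    grid = {
        "loci": [lv for lv in (100, 1000, ds.n_loci // 2) if lv <= ds.n_loci],
        "individuals": [lv for lv in (3, 6, 9) if lv <= n_ind_min],
        "populations": [lv for lv in (5, 10, 20, 30, 40) if lv <= ds.n_pops],
        "tradeoff": [(i, p) for i, p in ((3, 49), (6, 24), (9, 10))
                     if i <= n_ind_min and p <= ds.n_pops],
    }
    summaries = []
    for axis, levels in grid.items():
        for lv in levels:
            design = SamplingDesign(axis=axis, level=lv,
                                    n_replicates=args.replicates,
                                    seed=args.seed)
            tab = run_design(ds, meta, design, suite)
            tab.to_csv(os.path.join(args.out_dir,
                                    f"replicates_{axis}_{lv}.csv"), index=False)
            summ = summarize_replicates(tab, ref)
            summ.insert(0, "axis", axis)
            summ.insert(1, "level", str(lv))
            summaries.append(summ)
            hs_err = summ.set_index("statistic").loc["mean_hs",
                                                     "rel_error_of_mean"]
            print(f"{axis}={lv}: mean-Hs relative error {hs_err:+.4f}")
    out = pd.concat(summaries, ignore_index=True)
    out.to_csv(os.path.join(args.out_dir, "design_summaries.csv"), index=False)
    print(f"wrote {args.out_dir}/design_summaries.csv "
          f"({len(out)} statistic x design rows)")


if __name__ == "__main__":
    main()
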