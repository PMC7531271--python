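"""Simulate the two hierarchical demographic models and write the datasets.

Builds the 50-deme high- and low-gene-flow models (two 25-deme clusters,
15 diploids per deme), simulates ascertained SNP genotypes plus a
22-locus microsatellite dataset, generates the synthetic landscape
metadata, and writes everything under results/data/ as VCF / CSV.

The locus count defaults to 2,000 (i.i.d. loci; enough to pin every
mean statistic) to keep this desk-scale; pass --n-loci 30000 for the
full-size datasets.
"""

import argparse
import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from minsamp import (build_hierarchical_model, generate_landscape,
                     pool_frequencies, simulate_microsat_genotypes,
                     simulate_snp_genotypes)
from minsamp.io import (write_metadata_csv, write_microsat_csv,
                        write_pool_csv, write_vcf)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-loci", type=int, default=2000)
    ap.add_argument("--out-dir", default="results/data")
    args = ap.parse_args()
    os.makedirs(args.out_dir, exist_ok=True)

    for regime in ("high", "low"):
        model = build_hierarchical_model(regime, seed=args.seed)
        meta, model = generate_landscape(model, mode="island",
                                         seed=args.seed + 1)
        ds = simulate_snp_genotypes(model, n_loci=args.n_loci,
                                    seed=args.seed + 2)
        prefix = os.path.join(args.out_dir, f"sim_{regime}")
        write_vcf(ds, f"{prefix}.vcf")
        write_metadata_csv(meta, f"{prefix}_metadata.csv")
        with open(f"{prefix}_model.json", "w") as fh:
            json.dump(model.to_dict(), fh)
        write_pool_csv(pool_frequencies(ds), f"{prefix}_pooled.csv")
        print(f"{regime}-flow: {ds.n_pops} pops x {ds.n_loci} SNPs -> {prefix}.vcf")

    # microsatellite-style companion dataset (22 loci, stepwise mutation)
    model = build_hierarchical_model("high", seed=args.seed)
    msat = simulate_microsat_genotypes(model, n_loci=22, seed=args.seed + 3)
    write_microsat_csv(msat, os.path.join(args.out_dir, "sim_microsat.csv"))
    print(f"microsatellites: {msat.n_pops} pops x 22 loci -> sim_microsat.csv")


if __name__ == "__main__":
    main()
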