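"""End-to-end pipeline: simulate/load -> reference statistics ->
subsampling design grid -> summaries -> optional outlier experiment.

A :class:`RunConfig` fully specifies a run (it is validated up front and
serialized next to the outputs together with a content hash, so any
archived run can be reproduced exactly from its own output directory).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import simulate as msim
from . import stats as mstats
from .datasets import PopMetadata
from .subsampling import (SamplingDesign, StatSuite, compute_suite,
                          run_design, summarize_replicates)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``genotypes_path`` (+ optional ``metadata_path``) or a
    simulation block (``sim_regime`` etc.) must be given.  The design
    grid maps axis names to lists of levels.
    """

    out_dir: str
    seed: int = 0
    # simulation block
    sim_regime: str | None = "high"
    sim_n_loci: int = 1000
    sim_n_individuals: int = 15
    sim_landscape_mode: str = "island"
    sim_maf: float | None = None
    # or input files
    genotypes_path: str | None = None
    genotypes_format: str = "auto"
    metadata_path: str | None = None
    # designs
    designs: dict[str, list] = field(default_factory=dict)
    n_replicates: int = 100
    landscape_stats: bool = False
    # outlier experiment
    outlier_levels: list | None = None
    outlier_reps: int = 10
    outlier_n_loci: int | None = None
    outlier_n_null: int = 2000
    outlier_n_permutations: int = 500

    def validate(self) -> None:
        if self.genotypes_path is None and self.sim_regime is None:
            raise ValueError("config needs either input paths or a simulation block")
        for axis in self.designs:
            if axis not in ("loci", "individuals", "populations", "tradeoff"):
                raise ValueError(f"unknown design axis {axis!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d.pop("config_hash", None)
        return cls(**d)


def run_pipeline(config: RunConfig) -> str:
    """Execute the pipeline; returns the output directory.

    Every stage is logged with its seed and timing; a stage failure is
    recorded with the stage name and re-raised after partial results
    are flushed.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    chash = config.content_hash()
    log_path = os.path.join(config.out_dir, "run.log")
    log_fh = open(log_path, "w")

    def log(msg: str) -> None:
        stamp = time.strftime("%H:%M:%S")
        log_fh.write(f"[{stamp}] {msg}\n")
        log_fh.flush()

    with open(os.path.join(config.out_dir, "config.yaml"), "w") as fh:
        fh.write(f"# config_hash: {chash}\n")
        fh.write(config.to_yaml())
    log(f"config hash {chash}, seed {config.seed}")

    stage = "inputs"
    try:
        if config.genotypes_path is not None:
            dataset = mio.load_genotypes(config.genotypes_path,
                                         config.genotypes_format)
            meta = (mio.load_metadata(config.metadata_path, dataset.pop_ids)
                    if config.metadata_path else None)
            log(f"loaded {dataset.n_pops} pops x {dataset.n_loci} loci "
                f"from {config.genotypes_path}")
        else:
            stage = "simulate"
            model = msim.build_hierarchical_model(regime=config.sim_regime,
                                                  seed=config.seed)
            meta, model = msim.generate_landscape(
                model, mode=config.sim_landscape_mode, seed=config.seed + 1)
            dataset = msim.simulate_snp_genotypes(
                model, n_loci=config.sim_n_loci,
                n_diploids_per_pop=config.sim_n_individuals,
                seed=config.seed + 2, maf=config.sim_maf)
            log(f"simulated {config.sim_regime}-flow model: "
                f"{dataset.n_pops} pops x {dataset.n_loci} loci")

        stage = "reference"
        suite = StatSuite(landscape=config.landscape_stats)
        reference = compute_suite(dataset, meta, suite)
        pd.DataFrame([reference]).to_csv(
            os.path.join(config.out_dir, "reference_stats.csv"), index=False)
        log(f"reference statistics: { {k: round(v, 5) for k, v in reference.items()} }")

        stage = "designs"
        summaries = []
        for axis, levels in config.designs.items():
            for level in levels:
                lv = tuple(level) if axis == "tradeoff" else level
                design = SamplingDesign(axis=axis, level=lv,
                                        n_replicates=config.n_replicates,
                                        seed=config.seed + 10)
                t0 = time.time()
                table = run_design(dataset, meta, design, suite)
                name = f"replicates_{axis}_{lv}".replace(" ", "")
                table.to_csv(os.path.join(config.out_dir, f"{name}.csv"),
                             index=False)
                summ = summarize_replicates(table, reference)
                summ.insert(0, "axis", axis)
                summ.insert(1, "level", str(lv))
                summaries.append(summ)
                log(f"design {axis}={lv}: {config.n_replicates} replicates "
                    f"in {time.time() - t0:.1f}s")
        if summaries:
            pd.concat(summaries, ignore_index=True).to_csv(
                os.path.join(config.out_dir, "design_summaries.csv"), index=False)

        if config.outlier_levels:
            stage = "outliers"
            from .outliers import population_count_experiment
            if meta is None:
                raise ValueError("outlier experiment needs metadata")
            levels = [None if str(l) == "all" else int(l)
                      for l in config.outlier_levels]
            t0 = time.time()
            table = population_count_experiment(
                dataset, meta, levels=levels, reps=config.outlier_reps,
                n_loci=config.outlier_n_loci, n_null=config.outlier_n_null,
                n_permutations=config.outlier_n_permutations,
                seed=config.seed + 20)
            table.to_csv(os.path.join(config.out_dir, "outlier_experiment.csv"),
                         index=False)
            with open(os.path.join(config.out_dir,
                                   "outlier_intersections.json"), "w") as fh:
                json.dump({"per_level": table.attrs["intersection_per_level"],
                           "all": table.attrs["intersection_all"]}, fh, indent=2)
            log(f"outlier experiment in {time.time() - t0:.1f}s")
    except Exception as exc:                            # noqa: BLE001
        log(f"FAILED at stage {stage}: {exc!r}")
        log_fh.close()
        raise
    log("done")
    log_fh.close()
    return config.out_dir
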