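#!/usr/bin/env python
"""Simulate the synthetic study cohorts and write them to disk.

Generates the discovery cohort (103 tumors, planted 4-module VI signature,
two-site batch effect), an external validation cohort measuring the same
genes with a cohort-wide shift, two Visium-like sections (one VI+ with an
invaded focus and a section-wide angioinvasive background, one VI-), and a
63-tumor two-region multi-region cohort.  Everything downstream reads these
files, so the whole analysis is reproducible from this script plus a seed.
"""

import argparse
import json
from pathlib import Path

from visig import (SimDesign, generate_bulk_cohort, generate_multiregion,
                   generate_spot_grid, generate_survival, stage_seed,
                   write_count_matrix, write_spot_grid)
from visig.simulate import VI_BACKGROUND_LOG2, default_layout


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=str, default="results/data")
    args = parser.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    design = SimDesign(n_samples=103)
    gene_seed = stage_seed(args.seed, "genes")

    counts, samples, truth = generate_bulk_cohort(
        design, seed=stage_seed(args.seed, "discovery"), gene_seed=gene_seed)
    write_count_matrix(counts, out / "discovery_counts.tsv")
    samples.to_csv(out / "discovery_samples.tsv", sep="\t")
    truth.gene_cluster.to_csv(out / "planted_clusters.tsv", sep="\t")
    print(f"discovery: {counts.shape[0]} genes x {counts.shape[1]} samples; "
          f"grades {samples['grade'].value_counts().to_dict()}")

    val_design = SimDesign(n_samples=60)
    val_counts, val_samples, val_truth = generate_bulk_cohort(
        val_design, seed=stage_seed(args.seed, "validation"),
        gene_seed=gene_seed, cohort_shift_logsd=0.3, sample_prefix="V")
    surv = generate_survival(val_truth.sample_score, beta=2.0,
                             censor_rate=0.3,
                             seed=stage_seed(args.seed, "survival"))
    val_samples = val_samples.join(surv)
    write_count_matrix(val_counts, out / "validation_counts.tsv")
    val_samples.to_csv(out / "validation_samples.tsv", sep="\t")
    print(f"validation: {val_counts.shape[1]} samples, "
          f"{int(surv['event'].sum())} events")

    spot_design = SimDesign(n_genes=800)
    vi_pos, _ = generate_spot_grid(
        spot_design, seed=stage_seed(args.seed, "spots_pos"), nx=24, ny=24,
        sample_id="VIpos", background=VI_BACKGROUND_LOG2)
    layout_neg = [r for r in default_layout(24, 24) if r.label != "vi_focus"]
    vi_neg, _ = generate_spot_grid(
        spot_design, layout=layout_neg,
        seed=stage_seed(args.seed, "spots_neg"), nx=24, ny=24,
        sample_id="VIneg")
    for name, grid in (("vipos", vi_pos), ("vineg", vi_neg)):
        write_spot_grid(grid, out / f"spots_{name}_counts.tsv",
                        out / f"spots_{name}_positions.tsv",
                        out / f"spots_{name}_annotations.tsv")
    print(f"sections: VI+ {vi_pos.n_spots} spots "
          f"({(vi_pos.labels == 'vi_focus').sum()} in focus), "
          f"VI- {vi_neg.n_spots} spots")

    mr_counts, mr_samples, _ = generate_multiregion(
        design, n_tumors=63, regions_per_tumor=2,
        seed=stage_seed(args.seed, "multiregion"), gene_seed=gene_seed)
    write_count_matrix(mr_counts, out / "multiregion_counts.tsv")
    mr_samples.to_csv(out / "multiregion_samples.tsv", sep="\t")
    print(f"multi-region: {mr_samples['tumor_id'].nunique()} tumors, "
          f"{mr_counts.shape[1]} regions")

    (out / "manifest.json").write_text(json.dumps(
        {"seed": args.seed, "gene_seed": gene_seed,
         "n_genes": design.n_genes,
         "cluster_sizes": list(design.cluster_sizes)}, indent=1))


if __name__ == "__main__":
    main()
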