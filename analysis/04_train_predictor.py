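#!/usr/bin/env python
"""Train and honestly evaluate the 48-gene VI predictor.

Runs the nested cross-validation (stratified 70/30 outer splits, signature
re-derived within every training split, 5-fold inner ridge-penalty search),
then fits the final ridge-logit model on the full discovery cohort and
serializes it as JSON.
"""

import argparse
from pathlib import Path

import pandas as pd

from visig import (PipelineConfig, auroc, nested_cv, predict_scores,
                   read_count_matrix, stage_seed, train_ridge_logit)
from visig.predictor import derive_panel, feature_importance


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--data", type=str, default="results/data")
    parser.add_argument("--out", type=str, default="results/predictor")
    parser.add_argument("--outer-iters", type=int, default=None)
    args = parser.parse_args()
    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(global_seed=args.seed)

    counts = read_count_matrix(data / "discovery_counts.tsv")
    samples = pd.read_csv(data / "discovery_samples.tsv", sep="\t",
                          index_col=0)

    outer = args.outer_iters or cfg.outer_iters
    cv = nested_cv(counts, samples, cfg,
                   seed=stage_seed(args.seed, "nested_cv"),
                   outer_iters=outer)
    cv.to_csv(out / "nested_cv.tsv", sep="\t")
    print(f"nested CV ({outer} iterations): mean held-out AUROC "
          f"{cv['test_auroc'].mean():.3f} (SD {cv['test_auroc'].std():.3f})")

    panel, de, clusters, expr = derive_panel(counts, samples, cfg)
    model = train_ridge_logit(expr.values.loc[panel],
                              samples["vi"].astype(int),
                              inner_folds=cfg.inner_folds,
                              seed=stage_seed(args.seed, "final_fit"))
    model.to_json(out / "model.json")
    perf = auroc(predict_scores(model, expr), samples["vi"].astype(int),
                 n_boot=cfg.n_boot_auroc,
                 seed=stage_seed(args.seed, "train_auroc"))
    print(f"final model: lambda={model.penalty:.3g}, training AUROC "
          f"{perf['auroc']:.3f} (95% CI {perf['ci_low']:.3f}-"
          f"{perf['ci_high']:.3f})")

    table, ks = feature_importance(model, clusters)
    table.to_csv(out / "feature_importance.tsv", sep="\t")
    ks.to_csv(out / "cluster_rank_ks.tsv", sep="\t")
    top = table.index[0]
    print(f"top-ranked panel gene: {top} "
          f"(cluster {int(table['cluster'].iloc[0])})")


if __name__ == "__main__":
    main()
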