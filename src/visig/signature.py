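"""Signature clustering and sample/spot-level scoring.

The differentially expressed genes are partitioned into co-expression
clusters by Ward-criterion hierarchical clustering on Euclidean distances of
per-gene z-scored expression, with the tree cut at a fixed k and cluster
indices re-ordered by descending mean log fold-change so the last cluster is
the down-regulated one.

Two scoring schemes are provided: the bulk mean-z-score (mean over the set of
per-gene z-scores against fixed reference statistics) and the spot-level
module score (mean set-gene expression minus the mean of expression-matched
control genes sampled from abundance bins), plus the up-minus-down
combination used for predictor-gene enrichment maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .io import GeneSetCollection

logger = logging.getLogger("visig")

__all__ = [
    "SignatureClusters",
    "cluster_signature",
    "mean_zscore_score",
    "module_score",
    "updown_score",
]


@dataclass
class SignatureClusters:
    """Partition of the signature genes with per-cluster VI direction."""

    assignments: pd.Series           # gene -> cluster index (1..k)
    directions: Dict[int, str]       # cluster -> "up" | "down"
    linkage: Optional[np.ndarray] = None

    @property
    def k(self) -> int:
        return int(self.assignments.max())

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def genes(self, cluster: int) -> List[str]:
        return list(self.assignments.index[self.assignments == cluster])

    def to_gene_sets(self, prefix: str = "cluster") -> GeneSetCollection:
        sets = {f"{prefix}{c}": self.genes(c)
                for c in range(1, self.k + 1) if self.genes(c)}
        descriptions = {f"{prefix}{c}": self.directions.get(c, "")
                        for c in range(1, self.k + 1)}
        return GeneSetCollection(sets=sets, descriptions=descriptions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": self.assignments,
            "direction": self.assignments.map(self.directions),
        })


def cluster_signature(expr: pd.DataFrame, k: int,
                      logfc: Optional[pd.Series] = None) -> SignatureClusters:
    """Ward-criterion hierarchical clustering of signature genes.

    ``expr`` is gene × sample expression restricted to the significant genes;
    rows are z-scored before the Euclidean distances are computed.  The tree
    is cut to exactly ``k`` clusters; if ``logfc`` is given, cluster indices
    are ordered by descending mean log fold-change (so the down-regulated
    cluster comes last) and directions are the sign of that mean.
    """
    n_genes = expr.shape[0]
    if k > n_genes:
        raise ValueError(f"k={k} exceeds the {n_genes} signature genes")
    values = expr.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd <= 0, 1.0, sd)
    z = (values - mean) / sd

    if n_genes == 1:
        raw = np.array([1])
        linkage = None
    else:
        linkage = sch.linkage(z, method="ward")
        raw = sch.fcluster(linkage, t=k, criterion="maxclust")

    # order cluster labels by descending mean logFC
    if logfc is not None:
        fc = logfc.reindex(expr.index).to_numpy(float)
        order = sorted(set(raw),
                       key=lambda c: -np.nanmean(fc[raw == c]))
    else:
        order = sorted(set(raw))
    relabel = {old: new for new, old in enumerate(order, start=1)}
    assignments = pd.Series([relabel[c] for c in raw], index=expr.index,
                            name="cluster")

    directions: Dict[int, str] = {}
    for c in sorted(set(assignments)):
        if logfc is not None:
            mean_fc = float(np.nanmean(
                logfc.reindex(expr.index).to_numpy(float)[assignments == c]))
            directions[c] = "up" if mean_fc >= 0 else "down"
        else:
            directions[c] = "up"
    logger.info("cluster_signature: %d genes into %d clusters, sizes %s",
                n_genes, len(set(assignments)),
                assignments.value_counts().sort_index().tolist())
    return SignatureClusters(assignments=assignments, directions=directions,
                             linkage=linkage)


def mean_zscore_score(expr: pd.DataFrame, gene_set: Sequence[str],
                      ref_mean: pd.Series, ref_sd: pd.Series) -> pd.Series:
    """Mean per-gene z-score of a gene set against reference statistics.

    The reference mean/SD come from a stated cohort (the training cohort by
    default) and are reused verbatim when scoring external cohorts.  Set
    genes missing from ``expr``, or with zero reference SD, are dropped with
    a warning.
    """
    present = [g for g in gene_set if g in expr.index]
    missing = len(gene_set) - len(present)
    if missing:
        logger.warning("mean_zscore_score: %d set gene(s) not in expression",
                       missing)
    usable = [g for g in present if ref_sd.get(g, 0.0) > 0]
    if len(usable) < len(present):
        logger.warning("mean_zscore_score: %d gene(s) dropped for zero "
                       "reference SD", len(present) - len(usable))
    if not usable:
        raise ValueError("no usable genes in set")
    sub = expr.loc[usable]
    z = sub.sub(ref_mean.loc[usable], axis=0).div(ref_sd.loc[usable], axis=0)
    return z.mean(axis=0)


def module_score(spot_expr: pd.DataFrame, gene_set: Sequence[str],
                 n_bins: int = 24, n_ctrl: int = 100, seed: int = 0,
                 control_pool: Optional[Sequence[str]] = None) -> pd.Series:
    """Binned-control module score on log-normalized spot expression.

    All measured genes are binned into ``n_bins`` of equal size by average
    expression across spots.  For each set gene, ``n_ctrl`` control genes are
    sampled from its bin (seeded; without replacement when the bin is large
    enough, with replacement otherwise).  The score per spot is the mean of
    the set genes minus the mean of all sampled controls.  ``control_pool``
    restricts where controls may be drawn from (used by tests to force
    degenerate controls).
    """
    present = [g for g in gene_set if g in spot_expr.index]
    if not present:
        raise ValueError("gene set has no overlap with measured genes")
    rng = np.random.default_rng(seed)

    avg = spot_expr.mean(axis=1)
    n_bins_eff = min(n_bins, len(avg))
    # equal-frequency bins on the rank of average expression
    ranks = avg.rank(method="first")
    bins = np.ceil(ranks / len(avg) * n_bins_eff).astype(int)

    pool_index = (spot_expr.index if control_pool is None
                  else pd.Index([g for g in control_pool
                                 if g in spot_expr.index]))
    controls: List[str] = []
    for gene in present:
        bin_id = bins.loc[gene]
        candidates = [g for g in avg.index[bins == bin_id] if g in pool_index]
        if not candidates:
            candidates = list(pool_index)
        replace = len(candidates) < n_ctrl
        chosen = rng.choice(np.array(candidates, dtype=object),
                            size=n_ctrl, replace=replace)
        controls.extend(chosen.tolist())

    score = (spot_expr.loc[present].mean(axis=0)
             - spot_expr.loc[controls].to_numpy(float).mean(axis=0))
    return pd.Series(score, index=spot_expr.columns, name="module_score")


def updown_score(score_up: pd.Series, score_down: pd.Series) -> pd.Series:
    """Up-module minus down-module score, elementwise on shared units."""
    if not score_up.index.equals(score_down.index):
        raise ValueError("scores must be on the same units")
    return score_up - score_down
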