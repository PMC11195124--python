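"""Preranked gene-set enrichment and Fisher over-representation.

The enrichment score is the classic weighted Kolmogorov–Smirnov running-sum
statistic: walking the ranking from top to bottom, hits increment the sum in
proportion to |score|^weight (normalized to one over the set) and misses
decrement it by 1/(N - Nh); the ES is the signed maximum deviation.
Significance comes from seeded gene-label permutations with a one-sided
pseudo-counted p toward the observed sign, BH-adjusted across sets
(Bonferroni optionally).  Over-representation uses the one-sided Fisher
exact test on the 2x2 overlap table against a stated gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .diffexpr import bh_fdr
from .io import GeneSetCollection

logger = logging.getLogger("visig")

__all__ = ["rank_genes", "enrichment_score", "preranked_gsea", "fisher_ora"]


def rank_genes(de: pd.DataFrame) -> pd.Series:
    """Rank genes by -log10(p) * sign(logFC), descending.

    ``de`` is a differential-expression table indexed by gene with columns
    ``PValue`` and ``logFC``.  Zero p-values are clamped to the smallest
    positive double with a warning; ties are broken lexicographically by gene
    identifier for determinism.
    """
    p = de["PValue"].to_numpy(float).copy()
    if np.isnan(p).any():
        raise ValueError("ranking requires non-NA p-values")
    n_zero = int((p == 0).sum())
    if n_zero:
        logger.warning("rank_genes: %d zero p-value(s) clamped", n_zero)
        p[p == 0] = np.finfo(float).tiny
    score = -np.log10(p) * np.sign(de["logFC"].to_numpy(float))
    ranked = pd.Series(score, index=de.index, name="rank_score")
    order = sorted(ranked.index, key=lambda g: (-ranked[g], g))
    return ranked.loc[order]


def enrichment_score(ranked: pd.Series, gene_set: Sequence[str],
                     weight: float = 1.0):
    """Weighted KS enrichment score and its running sum.

    Returns ``(es, running, hit_mask)`` where ``es`` is the signed maximum
    deviation of the running sum and ``hit_mask`` marks set members along the
    ranking.
    """
    genes = pd.Index(ranked.index)
    hit = np.asarray(genes.isin(list(set(gene_set))))
    n, nh = len(genes), int(hit.sum())
    if nh < 1:
        raise ValueError("gene set has no genes in the ranking")
    if nh == n:
        raise ValueError("gene set covers the entire ranking")
    weights = np.abs(ranked.to_numpy(float)) ** weight
    hit_weights = np.where(hit, weights, 0.0)
    total = hit_weights.sum()
    if total <= 0:
        hit_weights = hit.astype(float)
        total = hit_weights.sum()
    increments = np.where(hit, hit_weights / total, -1.0 / (n - nh))
    running = np.cumsum(increments)
    es = float(running[np.argmax(np.abs(running))])
    return es, running, hit


def preranked_gsea(ranked: pd.Series, sets: GeneSetCollection,
                   weight: float = 1.0, nperm: int = 1000, seed: int = 0,
                   adjust: str = "bh") -> pd.DataFrame:
    """Permutation GSEA over a ranked list for every supplied set.

    Per set: the ES on the observed ranking; ``nperm`` seeded permutations of
    set membership (random same-size draws from the ranked genes); a
    one-sided p toward the observed sign with a +1 pseudo-count; a normalized
    ES against the mean same-sign permutation magnitude; and the leading-edge
    genes (members at or before the ES extremum).  Sets with fewer than two
    ranked genes are skipped with a warning.
    """
    if adjust not in ("bh", "bonferroni"):
        raise ValueError("adjust must be 'bh' or 'bonferroni'")
    rng = np.random.default_rng(seed)
    genes = ranked.index
    rows = []
    for name, members in sets.items():
        present = [g for g in members if g in genes]
        if len(present) < 2:
            logger.warning("preranked_gsea: set %s has <2 ranked genes; "
                           "skipped", name)
            continue
        es, running, hit = enrichment_score(ranked, present, weight=weight)
        peak = int(np.argmax(np.abs(running)))
        hit_positions = np.flatnonzero(hit)
        if es >= 0:
            leading = [genes[i] for i in hit_positions if i <= peak]
        else:
            leading = [genes[i] for i in hit_positions if i >= peak]

        size = len(present)
        perm_es = np.empty(nperm)
        for b in range(nperm):
            perm = rng.choice(len(genes), size=size, replace=False)
            perm_set = genes[perm]
            perm_es[b] = enrichment_score(ranked, perm_set, weight=weight)[0]
        if es >= 0:
            same_sign = perm_es[perm_es >= 0]
            extreme = int((same_sign >= es).sum())
        else:
            same_sign = -perm_es[perm_es < 0]
            extreme = int((same_sign >= -es).sum())
        # one-sided toward the observed sign, normalized within the
        # same-sign permutations, +1 pseudo-count so p > 0 always
        p = (1.0 + extreme) / (1.0 + same_sign.size)
        nes = es / same_sign.mean() if same_sign.size else np.nan
        rows.append({"set": name, "size": size, "es": es, "nes": nes,
                     "pvalue": p, "leading_edge": ",".join(map(str, leading))})

    result = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "es", "nes", "pvalue", "leading_edge"])
    if len(result):
        if adjust == "bh":
            result["padj"] = bh_fdr(result["pvalue"].to_numpy())
        else:
            result["padj"] = np.minimum(result["pvalue"] * len(result), 1.0)
    else:
        result["padj"] = []
    return result


def fisher_ora(query: Sequence[str], universe: Sequence[str],
               sets: GeneSetCollection) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of a query gene list.

    ``query`` must be a subset of ``universe``; each set is intersected with
    the universe before the 2x2 table is built.  Returns odds ratios,
    hypergeometric-tail p-values and BH-adjusted p per set.
    """
    universe_set = set(universe)
    query_set = set(query)
    if not query_set <= universe_set:
        raise ValueError("query genes must be a subset of the universe")
    n_universe = len(universe_set)
    rows = []
    for name, members in sets.items():
        member_set = set(members) & universe_set
        overlap = len(query_set & member_set)
        query_only = len(query_set) - overlap
        set_only = len(member_set) - overlap
        neither = n_universe - overlap - query_only - set_only
        odds, p = fisher_exact([[overlap, query_only], [set_only, neither]],
                               alternative="greater")
        rows.append({"set": name, "overlap": overlap, "set_size": len(member_set),
                     "odds_ratio": odds, "pvalue": p})
    result = pd.DataFrame(rows).set_index("set")
    result["padj"] = bh_fdr(result["pvalue"].to_numpy())
    return result
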