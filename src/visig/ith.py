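"""Multi-region robustness of the predictor to intra-tumor heterogeneity.

Every tumor is downsampled to two regions; intra-tumor heterogeneity is the
absolute score difference within those pairs, contrasted (Wilcoxon rank-sum)
against inter-tumor differences from an equal number of random cross-tumor
region pairs.  The paired-region Spearman correlation of scores, and the
ranking of genes by their region-region expression correlation (fed to
preranked enrichment with the predictor panel as the set), complete the
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

logger = logging.getLogger("visig")

__all__ = [
    "RegionPairing",
    "sample_region_pairs",
    "ith_statistics",
    "regionwise_gene_correlation",
]


@dataclass
class RegionPairing:
    """Unordered region pairs, one draw of a resampling scheme."""

    pairs: List[Tuple[str, str]]
    mode: str                       # "intra" or "inter"
    seed: int

    def __post_init__(self) -> None:
        seen: set = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"degenerate pair ({a}, {a})")
        if self.mode == "intra":
            for a, b in self.pairs:
                if a in seen or b in seen:
                    raise ValueError("region reused within an intra draw")
                seen.update((a, b))

    def regions(self) -> List[str]:
        return [r for pair in self.pairs for r in pair]


def sample_region_pairs(samples: pd.DataFrame, mode: str = "intra",
                        n_draws: Optional[int] = None,
                        seed: int = 0) -> RegionPairing:
    """Seeded random region pairs within or across tumors.

    ``samples`` must carry ``tumor_id`` indexed by region.  ``mode='intra'``
    draws one unordered pair of regions per tumor (tumors with fewer than two
    regions are excluded with a warning); ``mode='inter'`` draws ``n_draws``
    pairs of regions from two distinct tumors (default: one per tumor, so the
    intra and inter samples are the same size).
    """
    rng = np.random.default_rng(seed)
    groups = samples.groupby("tumor_id").groups
    tumors = sorted(groups)
    if mode == "intra":
        pairs = []
        for tumor in tumors:
            regions = list(groups[tumor])
            if len(regions) < 2:
                logger.warning("tumor %s has <2 regions; excluded", tumor)
                continue
            a, b = rng.choice(regions, size=2, replace=False)
            pairs.append((str(a), str(b)))
        if not pairs:
            raise ValueError("no tumor has two regions")
    elif mode == "inter":
        if len(tumors) < 2:
            raise ValueError("inter-tumor pairs need at least 2 tumors")
        n_draws = n_draws if n_draws is not None else len(tumors)
        pairs = []
        for _ in range(n_draws):
            t1, t2 = rng.choice(len(tumors), size=2, replace=False)
            r1 = rng.choice(list(groups[tumors[t1]]))
            r2 = rng.choice(list(groups[tumors[t2]]))
            pairs.append((str(r1), str(r2)))
    else:
        raise ValueError("mode must be 'intra' or 'inter'")
    return RegionPairing(pairs=pairs, mode=mode, seed=seed)


def ith_statistics(scores: pd.Series, intra: RegionPairing,
                   inter: RegionPairing, seed: int = 0) -> dict:
    """Intra- vs inter-tumor absolute score differences and pair correlation.

    Returns the two |Δ| samples, a two-sided Wilcoxon rank-sum p between
    them, and the Spearman correlation of (region A, region B) scores across
    the intra pairs with the A/B assignment randomized (seeded).
    """
    missing = [r for r in intra.regions() + inter.regions()
               if r not in scores.index]
    if missing:
        raise ValueError(f"scores missing for region(s): {missing[:5]}")
    rng = np.random.default_rng(seed)

    intra_diff = np.array([abs(scores[a] - scores[b]) for a, b in intra.pairs])
    inter_diff = np.array([abs(scores[a] - scores[b]) for a, b in inter.pairs])
    wilcoxon_p = float(mannwhitneyu(intra_diff, inter_diff,
                                    alternative="two-sided").pvalue)

    a_scores, b_scores = [], []
    for a, b in intra.pairs:
        if rng.random() < 0.5:
            a, b = b, a
        a_scores.append(scores[a])
        b_scores.append(scores[b])
    if np.ptp(a_scores) == 0 and np.ptp(b_scores) == 0:
        rho, rho_p = 1.0, 0.0  # identical regions per tumor
    else:
        rho, rho_p = spearmanr(a_scores, b_scores)
    return {
        "intra_abs_diff": intra_diff,
        "inter_abs_diff": inter_diff,
        "wilcoxon_p": wilcoxon_p,
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
    }


def regionwise_gene_correlation(expr: pd.DataFrame, intra: RegionPairing,
                                seed: int = 0) -> pd.Series:
    """Rank genes by Spearman correlation between paired regions.

    ``expr`` is gene × region expression (already filtered for low
    expression).  For each gene the correlation is computed across tumors
    between the region-A and region-B values, with the A/B assignment
    randomized per tumor (seeded).  Returns the correlations sorted
    descending (ties broken by gene ID), ready for preranked enrichment.
    """
    if len(intra.pairs) < 10:
        raise ValueError("need at least 10 tumors for a stable ranking")
    rng = np.random.default_rng(seed)
    pairs = []
    for a, b in intra.pairs:
        if rng.random() < 0.5:
            a, b = b, a
        pairs.append((a, b))
    a_mat = expr.loc[:, [a for a, _ in pairs]].to_numpy(float)
    b_mat = expr.loc[:, [b for _, b in pairs]].to_numpy(float)

    # per-gene Spearman = Pearson of ranks across tumors
    def rank_rows(m):
        return np.apply_along_axis(
            lambda row: pd.Series(row).rank().to_numpy(), 1, m)

    ra, rb = rank_rows(a_mat), rank_rows(b_mat)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (ra * rb).sum(axis=1) / denom, 0.0)
    ranked = pd.Series(rho, index=expr.index, name="region_correlation")
    order = sorted(ranked.index, key=lambda g: (-ranked[g], g))
    return ranked.loc[order]
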