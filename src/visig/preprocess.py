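"""Bulk expression normalization, QC filters, and cross-cohort harmonization.

Library-size normalization follows the trimmed-mean-of-M-values (TMM) scheme:
a reference column is chosen by upper-quartile proximity to the cohort mean,
per-sample scaling factors are weighted trimmed means of gene-wise log ratios
against that reference, and the factors are rescaled to geometric mean one.
Expression is carried downstream as log2 counts-per-million with a
library-size-proportional pseudo-count.

Cross-cohort harmonization uses a reference-batch location/scale adjustment on
the logCPM scale: non-reference batches are standardized against the
reference-batch per-gene model and mapped onto it, optionally with parametric
empirical-Bayes shrinkage of the per-gene batch effects.  The reference batch
is returned bit-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("visig")

__all__ = [
    "ExprMatrix",
    "tmm_factors",
    "logcpm",
    "filter_genes",
    "filter_samples_quality",
    "reference_batch_adjust",
]


@dataclass
class ExprMatrix:
    """Gene × sample log2-CPM with its normalization provenance."""

    values: pd.DataFrame
    lib_size: pd.Series
    norm_factors: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite logCPM entries")
        log_gm = np.log(self.norm_factors.to_numpy(float)).mean()
        if abs(log_gm) > 1e-9:
            raise ValueError("normalization factors must multiply to 1")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.30,
                sum_trim: float = 0.05) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    The reference sample is the column whose 75th percentile of
    counts/library-size is closest to the cohort mean of those percentiles.
    For every sample, genes expressed in both it and the reference contribute
    a log2 ratio of depth-normalized counts (M) and an average abundance (A);
    the top and bottom ``logratio_trim`` of M and ``sum_trim`` of A are
    discarded and the factor is 2 to the delta-method precision-weighted mean
    of the surviving M values.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    values = counts.to_numpy(float)
    lib = values.sum(axis=0)
    zero = np.flatnonzero(lib <= 0)
    if zero.size:
        raise ValueError(
            f"sample(s) with all-zero counts: {list(counts.columns[zero])}")

    f75 = np.quantile(values / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        factors[j] = _tmm_pair(values[:, j], values[:, ref_idx],
                               lib[j], lib[ref_idx],
                               logratio_trim, sum_trim)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, sum_trim: float) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method precision of M under binomial sampling
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.allclose(m, 0, atol=1e-10):
        return 1.0

    n = m.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


# ---------------------------------------------------------------------------
# logCPM
# ---------------------------------------------------------------------------

def logcpm(counts: pd.DataFrame, factors: Optional[pd.Series] = None,
           prior_count: float = 2.0) -> ExprMatrix:
    """log2 counts-per-million on TMM-effective library sizes.

    The pseudo-count is scaled proportionally to each sample's effective
    library size (``prior * L_j / mean(L)``) so that the offset is comparable
    across depths, and the library size in the denominator is inflated by
    twice the scaled prior — the conventional logCPM definition.
    """
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    values = counts.to_numpy(float)
    lib = values.sum(axis=0) * factors.reindex(counts.columns).to_numpy(float)
    if (lib <= 0).any():
        raise ValueError("non-positive effective library size")
    prior_scaled = prior_count * lib / lib.mean()
    cpm = (values + prior_scaled) / (lib + 2 * prior_scaled) * 1e6
    if (cpm <= 0).any():
        raise ValueError("non-positive CPM; use prior_count > 0 for zero counts")
    frame = pd.DataFrame(np.log2(cpm), index=counts.index, columns=counts.columns)
    return ExprMatrix(values=frame,
                      lib_size=pd.Series(values.sum(axis=0), index=counts.columns,
                                         name="lib_size"),
                      norm_factors=factors.reindex(counts.columns))


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_genes(counts: pd.DataFrame, cpm_threshold: float = 1.0,
                 frac: float = 0.10) -> pd.DataFrame:
    """Keep genes with CPM > ``cpm_threshold`` in >= ceil(frac * n) samples."""
    values = counts.to_numpy(float)
    lib = values.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample(s) with zero library size")
    cpm = values / lib * 1e6
    need = math.ceil(frac * counts.shape[1])
    keep = (cpm > cpm_threshold).sum(axis=1) >= need
    logger.info("filter_genes: %d/%d genes retained (CPM>%g in >=%d samples)",
                int(keep.sum()), counts.shape[0], cpm_threshold, need)
    return counts.loc[keep]


def filter_samples_quality(quality: pd.Series, sd_threshold: float = 2.0) -> pd.Index:
    """Sample IDs whose quality score is within ``sd_threshold`` SDs of the mean.

    The mean and SD are computed once over all samples (no iterative
    re-filtering).  With zero variance every sample is retained.
    """
    if len(quality) < 3:
        raise ValueError("quality filter needs at least 3 samples")
    scores = quality.to_numpy(float)
    mean, sd = scores.mean(), scores.std(ddof=1)
    if sd == 0 or not np.isfinite(sd_threshold):
        return quality.index
    keep = np.abs(scores - mean) <= sd_threshold * sd
    removed = quality.index[~keep]
    if len(removed):
        logger.info("filter_samples_quality: removed %s", list(removed))
    return quality.index[keep]


# ---------------------------------------------------------------------------
# reference-batch adjustment
# ---------------------------------------------------------------------------

def reference_batch_adjust(expr: ExprMatrix, batches: pd.Series,
                           reference: str, shrink: bool = True) -> ExprMatrix:
    """Map non-reference batches onto the reference batch's per-gene model.

    Per gene, the reference batch defines a location ``alpha_g`` (mean) and a
    scale ``sigma_g`` (SD).  Each non-reference batch's standardized data
    ``z = (y - alpha) / sigma`` yields batch-effect estimates ``gamma_g``
    (mean) and ``delta2_g`` (variance); with ``shrink=True`` these are pooled
    across genes by the standard parametric empirical-Bayes scheme (normal
    prior on locations, inverse-gamma on scales, moment-matched, iterated to
    convergence).  Adjusted values are
    ``sigma * (z - gamma*) / sqrt(delta2*) + alpha``; reference-batch columns
    are returned bit-identical.
    """
    batches = batches.reindex(expr.samples)
    if batches.isna().any():
        raise ValueError("batch label missing for some samples")
    counts_per_batch = batches.value_counts()
    if reference not in counts_per_batch.index:
        raise ValueError(f"reference batch {reference!r} not present")
    small = counts_per_batch[counts_per_batch < 2]
    if len(small):
        raise ValueError(f"batch(es) with <2 samples: {list(small.index)}")

    values = expr.values.to_numpy(float)
    out = values.copy()
    ref_mask = (batches == reference).to_numpy()
    alpha = values[:, ref_mask].mean(axis=1)
    sigma = values[:, ref_mask].std(axis=1, ddof=1)
    sigma = np.where(sigma <= 0, 1.0, sigma)

    for batch in counts_per_batch.index:
        if batch == reference:
            continue
        mask = (batches == batch).to_numpy()
        z = (values[:, mask] - alpha[:, None]) / sigma[:, None]
        gamma = z.mean(axis=1)
        delta2 = z.var(axis=1, ddof=1)
        delta2 = np.where(delta2 <= 0, 1e-12, delta2)
        if shrink:
            gamma, delta2 = _eb_shrink(z, gamma, delta2)
        adjusted = (z - gamma[:, None]) / np.sqrt(delta2)[:, None]
        out[:, mask] = adjusted * sigma[:, None] + alpha[:, None]

    frame = pd.DataFrame(out, index=expr.genes, columns=expr.samples)
    return ExprMatrix(values=frame, lib_size=expr.lib_size,
                      norm_factors=expr.norm_factors)


def _eb_shrink(z: np.ndarray, gamma: np.ndarray, delta2: np.ndarray,
               tol: float = 1e-6, max_iter: int = 200):
    """Parametric empirical-Bayes pooling of per-gene batch effects.

    Normal prior on the location effects and inverse-gamma on the scale
    effects, hyperparameters moment-matched from the gene-wise estimates, then
    the usual coupled fixed-point iteration for the conditional posterior
    means.
    """
    n = z.shape[1]
    gamma_bar = gamma.mean()
    tau2 = gamma.var(ddof=1)
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    if s2 <= 0:
        return np.full_like(gamma, gamma_bar) if tau2 <= 0 else gamma, delta2
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    g_new, d_new = gamma.copy(), delta2.copy()
    for _ in range(max_iter):
        g_old, d_old = g_new, d_new
        if tau2 <= 0:
            g_new = np.full_like(gamma, gamma_bar)
        else:
            g_new = (n * tau2 * gamma + d_old * gamma_bar) / (n * tau2 + d_old)
        sse = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sse + b_prior) / (n / 2 + a_prior - 1)
        if (np.max(np.abs(g_new - g_old)) < tol
                and np.max(np.abs(d_new - d_old)) < tol):
            break
    return g_new, d_new
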