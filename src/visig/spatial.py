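"""Spot-level QC, normalization, and spatial statistics.

Includes the spot QC floor on detected genes, depth normalization with log1p,
kernel-weighted local correlation of per-spot score maps (a geographically
weighted statistic: each spot gets a correlation computed under weights that
decay with distance), mixed-model association of per-spot values with
pathology annotation, proximal/distal binning around a target annotation, and
the capture-area presence filter for deconvolved cell types.

Mixed models are REML linear mixed models with a random intercept per sample,
fitted with statsmodels; the high-grade contrast uses a maximum-likelihood
fit so the likelihood-ratio test for the tumor VI-status term is valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.spatial
from scipy.stats import chi2, rankdata
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import SpotGrid

logger = logging.getLogger("visig")

__all__ = [
    "spot_qc",
    "lognormalize_spots",
    "weighted_local_correlation",
    "LocalCorrMap",
    "region_association",
    "highgrade_vi_contrast",
    "distance_bins",
    "celltype_presence_filter",
]


def spot_qc(grid: SpotGrid, min_genes: int = 250) -> SpotGrid:
    """Drop spots with fewer than ``min_genes`` detected (non-zero) genes."""
    detected = (grid.counts.to_numpy() > 0).sum(axis=0)
    keep = detected >= min_genes
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("spot_qc: removed %d/%d spots (<%d detected genes)",
                    n_removed, grid.n_spots, min_genes)
    return grid.subset(grid.spot_ids[keep])


def lognormalize_spots(grid: SpotGrid, scale_target: float = 1e4) -> pd.DataFrame:
    """Depth-normalize each spot to ``scale_target`` total counts, then log1p."""
    values = grid.counts.to_numpy(float)
    depth = values.sum(axis=0)
    if (depth <= 0).any():
        raise ValueError("spot(s) with zero total counts; run spot_qc first")
    normalized = np.log1p(values / depth * scale_target)
    return pd.DataFrame(normalized, index=grid.counts.index,
                        columns=grid.counts.columns)


# ---------------------------------------------------------------------------
# spatially weighted correlation
# ---------------------------------------------------------------------------

@dataclass
class LocalCorrMap:
    """Per-spot local correlation between two score maps."""

    values: pd.Series                # per-spot coefficient (NaN where invalid)
    per_sample_mean: pd.Series       # mean over valid spots within a sample
    bandwidth: float
    kernel: str

    @property
    def overall_mean(self) -> float:
        """Mean of per-sample means (equal sample weighting)."""
        return float(self.per_sample_mean.mean())


def _kernel_weights(dist: np.ndarray, h: float, kernel: str) -> np.ndarray:
    if kernel == "bisquare":
        u = dist / h
        w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    elif kernel == "gaussian":
        w = np.exp(-0.5 * (dist / h) ** 2)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return w


def _weighted_corr(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    am = (w * a).sum() / wsum
    bm = (w * b).sum() / wsum
    cov = (w * (a - am) * (b - bm)).sum() / wsum
    va = (w * (a - am) ** 2).sum() / wsum
    vb = (w * (b - bm) ** 2).sum() / wsum
    if va <= 0 or vb <= 0:
        return np.nan
    return float(np.clip(cov / np.sqrt(va * vb), -1.0, 1.0))


def weighted_local_correlation(grid: SpotGrid, scores_a: pd.Series,
                               scores_b: pd.Series, bandwidth: float = 5.0,
                               kernel: str = "bisquare",
                               rank_transform: bool = True,
                               min_weighted: int = 3) -> LocalCorrMap:
    """Kernel-weighted local correlation of two per-spot score maps.

    The bandwidth is in spot-pitch units (``bandwidth * grid.pitch_um`` µm).
    With ``rank_transform`` the scores are globally rank-transformed first,
    giving a local Spearman analogue.  Spots within one sample only see other
    spots of the same sample.  A spot with fewer than ``min_weighted`` spots
    of positive weight gets NaN.
    """
    spots = grid.spot_ids
    a = scores_a.reindex(spots).to_numpy(float)
    b = scores_b.reindex(spots).to_numpy(float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("scores must be defined on every retained spot")
    h = bandwidth * grid.pitch_um
    out = np.full(len(spots), np.nan)
    samples = grid.sample_ids.to_numpy()
    coords = grid.coords

    for sample in pd.unique(samples):
        mask = samples == sample
        sa, sb = a[mask], b[mask]
        if rank_transform:
            sa = rankdata(sa)
            sb = rankdata(sb)
        sub_coords = coords[mask]
        dist = scipy.spatial.distance.cdist(sub_coords, sub_coords)
        weights = _kernel_weights(dist, h, kernel)
        local = np.full(mask.sum(), np.nan)
        for i in range(len(local)):
            w = weights[i]
            if (w > 0).sum() < min_weighted:
                continue
            local[i] = _weighted_corr(sa, sb, w)
        out[mask] = local

    values = pd.Series(out, index=spots, name="local_corr")
    per_sample = values.groupby(grid.sample_ids).mean()
    return LocalCorrMap(values=values, per_sample_mean=per_sample,
                        bandwidth=bandwidth, kernel=kernel)


# ---------------------------------------------------------------------------
# region association (mixed models)
# ---------------------------------------------------------------------------

def region_association(grid: SpotGrid, values: pd.Series,
                       reference_label: str = "normal_lung",
                       downsample_n: int = 200, seed: int = 0) -> pd.DataFrame:
    """Mixed-model association of a per-spot value with pathology annotation.

    Labels with fewer than ``downsample_n`` spots are dropped; the remaining
    labels are downsampled (seeded) to ``downsample_n`` spots each.  A linear
    mixed model ``value ~ label`` with a random intercept per sample is fit by
    REML; each label's Wald contrast against the reference is reported with
    Bonferroni-adjusted p-values.  Pass ``downsample_n=None`` (or ``inf``)
    to skip downsampling, which makes the estimate deterministic.
    """
    values = values.reindex(grid.spot_ids)
    if values.isna().any():
        raise ValueError("value missing for some spots")
    frame = pd.DataFrame({
        "value": values.to_numpy(float),
        "label": grid.labels.to_numpy(),
        "sample": grid.sample_ids.to_numpy(),
    })
    no_limit = downsample_n is None or np.isinf(downsample_n)
    if not no_limit:
        sizes = frame["label"].value_counts()
        keep_labels = sizes.index[sizes >= downsample_n]
        dropped = sorted(set(sizes.index) - set(keep_labels))
        if dropped:
            logger.info("region_association: dropped label(s) with <%d spots: %s",
                        downsample_n, dropped)
        frame = frame[frame["label"].isin(keep_labels)]
        rng = np.random.default_rng(seed)
        parts = []
        for label, part in frame.groupby("label", sort=True):
            idx = rng.choice(part.index.to_numpy(), size=downsample_n,
                             replace=False)
            parts.append(part.loc[np.sort(idx)])
        frame = pd.concat(parts)
    if reference_label not in set(frame["label"]):
        raise ValueError(f"reference label {reference_label!r} absent")
    labels = sorted(set(frame["label"]))
    if len(labels) < 2:
        raise ValueError("need at least two labels after filtering")

    if frame["value"].nunique() == 1:
        # degenerate: a constant response carries no association
        rows = [{"label": lab, "estimate": 0.0, "se": np.nan,
                 "pvalue": 1.0, "padj": 1.0}
                for lab in labels if lab != reference_label]
        return pd.DataFrame(rows).set_index("label")

    frame["label"] = pd.Categorical(
        frame["label"],
        categories=[reference_label] + [l for l in labels
                                        if l != reference_label])
    model = smf.mixedlm("value ~ C(label)", frame, groups=frame["sample"])
    fit = model.fit(reml=True)

    rows = []
    for label in labels:
        if label == reference_label:
            continue
        name = f"C(label)[T.{label}]"
        rows.append({
            "label": label,
            "estimate": float(fit.params[name]),
            "se": float(fit.bse[name]),
            "pvalue": float(fit.pvalues[name]),
        })
    result = pd.DataFrame(rows).set_index("label")
    result["padj"] = np.minimum(result["pvalue"] * len(result), 1.0)
    return result


def highgrade_vi_contrast(grids: Sequence[SpotGrid], scores: Sequence[pd.Series],
                          vi_status: Dict[str, int],
                          highgrade_labels: Sequence[str] = (
                              "solid", "cribriform", "micropapillary"),
                          ) -> Tuple[float, float]:
    """Tumor-VI-status effect on a score within high-grade-annotated spots.

    Spots carrying a high-grade pattern annotation are pooled across samples;
    a linear mixed model ``score ~ vi + pattern`` with a random intercept per
    sample is compared against the model without the VI term by a
    likelihood-ratio test (ML fits).  Returns ``(estimate, p)``.
    """
    frames = []
    for grid, score in zip(grids, scores):
        score = score.reindex(grid.spot_ids)
        mask = grid.labels.isin(highgrade_labels).to_numpy()
        if not mask.any():
            continue
        frames.append(pd.DataFrame({
            "score": score.to_numpy(float)[mask],
            "pattern": grid.labels.to_numpy()[mask],
            "sample": grid.sample_ids.to_numpy()[mask],
        }))
    if not frames:
        raise ValueError("empty stratum: no high-grade-annotated spots")
    frame = pd.concat(frames, ignore_index=True)
    frame["vi"] = frame["sample"].map(vi_status).astype(float)
    if frame["vi"].isna().any():
        raise ValueError("VI status missing for some samples")
    if frame["vi"].nunique() < 2:
        raise ValueError("need both VI+ and VI- samples in the stratum")

    full = smf.mixedlm("score ~ vi + C(pattern)", frame,
                       groups=frame["sample"]).fit(reml=False)
    reduced = smf.mixedlm("score ~ C(pattern)", frame,
                          groups=frame["sample"]).fit(reml=False)
    lr = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(chi2.sf(lr, df=1))
    return float(full.params["vi"]), p


# ---------------------------------------------------------------------------
# distance binning
# ---------------------------------------------------------------------------

def distance_bins(grid: SpotGrid, target_label: str = "vi_focus",
                  threshold_um: float = 1000.0) -> pd.Series:
    """Proximal/distal binning by distance to the nearest target-label spot.

    Distances are Euclidean between spot centers; spots carrying the label
    have distance 0 and are proximal; a spot is proximal iff its distance is
    <= ``threshold_um``.  A sample with no target-label spots is entirely
    proximal (tumors whose capture area missed the focus still count as
    containing it).  The grid must come from a single sample.
    """
    if grid.sample_ids.nunique() > 1:
        raise ValueError("distance_bins expects a single-sample grid")
    target = grid.labels == target_label
    if not target.any():
        return pd.Series("proximal", index=grid.spot_ids, name="distance_bin")
    tree = scipy.spatial.cKDTree(grid.coords[target.to_numpy()])
    dist, _ = tree.query(grid.coords)
    bins = np.where(dist <= threshold_um, "proximal", "distal")
    return pd.Series(bins, index=grid.spot_ids, name="distance_bin")


def celltype_presence_filter(predicted_counts: pd.DataFrame,
                             presence_frac: float = 0.20) -> pd.Index:
    """Cell types with >=1 predicted cell in enough capture areas.

    ``predicted_counts`` is cell-type × sample predicted cell counts; a type
    is kept when it has at least one predicted cell in at least
    ``ceil(presence_frac * n_samples)`` samples.
    """
    values = predicted_counts.to_numpy(float)
    if (values < 0).any():
        raise ValueError("predicted cell counts must be non-negative")
    need = int(np.ceil(presence_frac * predicted_counts.shape[1]))
    present_in = (values >= 1).sum(axis=1)
    keep = present_in >= need
    return predicted_counts.index[keep]
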