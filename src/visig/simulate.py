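"""Synthetic cohorts with the statistical structure the analysis assumes.

No patient-level data accompany the study design this package implements, so
every downstream stage is exercised on generated data with planted ground
truth: negative-binomial bulk counts with four vascular-invasion-associated
gene modules (three up-regulated, one down-regulated, with the intermediate
grade expressing an attenuated effect), a two-site batch effect, Visium-like
spot lattices with painted pathology regions and an invaded-vessel focus,
multi-region tumors sharing a latent score, and proportional-hazards survival
times.

All generators are pure functions of (design, seed): equal inputs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import SpotGrid

__all__ = [
    "SimDesign",
    "GroundTruth",
    "RegionSpec",
    "default_layout",
    "generate_bulk_cohort",
    "generate_spot_grid",
    "generate_multiregion",
    "generate_survival",
]

#: printed sizes of the four signature clusters in the discovery analysis
_CLUSTER_SIZES = (115, 37, 182, 140)


@dataclass
class SimDesign:
    """Knobs of the synthetic study.

    ``cluster_sizes`` default to the four planted module sizes (115/37/182/140
    genes); if they would not fit in ``n_genes`` they are rescaled
    proportionally.  ``effect_log2fc`` is the per-module log2 fold-change in
    VI-grade samples relative to LMP; NST samples express
    ``nst_attenuation`` of the full effect, LMP none.
    """

    n_genes: int = 2000
    n_samples: int = 100
    grade_probs: Tuple[float, float, float] = (0.22, 0.54, 0.24)  # LMP/NST/VI
    cluster_sizes: Tuple[int, int, int, int] = _CLUSTER_SIZES
    effect_log2fc: Tuple[float, float, float, float] = (1.0, 1.0, 1.0, -1.0)
    nst_attenuation: float = 0.4
    module_activity_sd: float = 0.5
    dispersion_logmean: float = float(np.log(0.15))
    dispersion_logsd: float = 0.5
    libsize_logmean: float = float(np.log(5e5))
    libsize_logsd: float = 0.3
    baseline_logsd: float = 1.2
    batch_shift_logsd: float = 0.15
    li_given_vi: float = 0.5
    li_given_novi: float = 0.15
    region_noise_sd: float = 0.1
    spot_pitch_um: float = 100.0
    spot_libsize_logmean: float = float(np.log(8000.0))
    spot_libsize_logsd: float = 0.3

    def __post_init__(self) -> None:
        if abs(sum(self.grade_probs) - 1.0) > 1e-9:
            raise ValueError("grade_probs must sum to 1")
        if len(self.cluster_sizes) != 4:
            raise ValueError("exactly four planted clusters are required")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be >= 1")
        if sum(self.cluster_sizes) > self.n_genes:
            scale = self.n_genes * 0.5 / sum(self.cluster_sizes)
            self.cluster_sizes = tuple(
                max(1, int(round(s * scale))) for s in self.cluster_sizes)
        if not all(np.isfinite(self.effect_log2fc)):
            raise ValueError("effect magnitudes must be finite")
        if not (0.0 <= self.nst_attenuation <= 1.0):
            raise ValueError("nst_attenuation must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure recorded for parameter-recovery tests."""

    gene_cluster: pd.Series                    # planted gene -> cluster (1..4)
    sample_score: Optional[pd.Series] = None   # per-sample latent VI score
    tumor_score: Optional[pd.Series] = None    # per-tumor latent (multi-region)
    region_labels: Optional[pd.Series] = None  # per-spot painted region
    survival_beta: Optional[float] = None

    def cluster_genes(self, cluster: int) -> List[str]:
        return list(self.gene_cluster.index[self.gene_cluster == cluster])


def _gene_baseline(design: SimDesign, rng: np.random.Generator) -> np.ndarray:
    """Relative gene abundances (sum 1) with log-normal spread."""
    raw = rng.lognormal(mean=0.0, sigma=design.baseline_logsd,
                        size=design.n_genes)
    return raw / raw.sum()


def _planted_clusters(design: SimDesign) -> pd.Series:
    genes = [f"G{i + 1:04d}" for i in range(design.n_genes)]
    cluster = np.zeros(design.n_genes, dtype=int)
    start = 0
    for c, size in enumerate(design.cluster_sizes, start=1):
        cluster[start:start + size] = c
        start += size
    return pd.Series(cluster, index=genes, name="cluster")


def _module_log2_shift(design: SimDesign, cluster: pd.Series,
                       score: np.ndarray,
                       rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """(genes x units) planted log2 shift given per-unit latent scores.

    Each cluster's per-unit activity is the shared latent score plus an
    independent Normal(0, module_activity_sd) component, making the four
    modules distinct co-expression patterns rather than copies of one factor.
    """
    effect = np.zeros(len(cluster))
    for c, fc in enumerate(design.effect_log2fc, start=1):
        effect[cluster.to_numpy() == c] = fc
    shift = np.zeros((len(cluster), len(score)))
    for c, fc in enumerate(design.effect_log2fc, start=1):
        activity = score.copy()
        if rng is not None and design.module_activity_sd > 0:
            activity = activity + rng.normal(0.0, design.module_activity_sd,
                                             size=len(score))
        shift[cluster.to_numpy() == c] = fc * activity
    return shift


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               phi: np.ndarray) -> np.ndarray:
    """NB(mu, phi) with Var = mu + phi mu^2 via the gamma–Poisson mixture."""
    phi = phi[:, None] if phi.ndim == 1 else phi
    shape = 1.0 / np.maximum(phi, 1e-12)
    lam = rng.gamma(shape=np.broadcast_to(shape, mu.shape),
                    scale=mu / np.broadcast_to(shape, mu.shape))
    return rng.poisson(lam).astype(np.int64)


def generate_bulk_cohort(design: SimDesign, seed: int,
                         gene_seed: Optional[int] = None,
                         cohort_shift_logsd: float = 0.0,
                         sample_prefix: str = "S"):
    """Simulate a bulk discovery-style cohort.

    Gene-level parameters (baseline abundances, dispersions, per-gene site
    shifts) come from their own stream keyed by ``gene_seed`` (default:
    ``seed``), so a validation cohort generated with the same ``gene_seed``
    but a new ``seed`` measures the same genes on new patients.
    ``cohort_shift_logsd`` adds a cohort-wide per-gene log2 shift (drawn from
    the sample stream) emulating a platform/site difference that the
    reference-batch harmonization has to remove.

    Returns ``(counts, samples, truth)`` where ``samples`` carries grade
    (LMP/NST/VI), the VI and LI flags, a two-site batch label, and a
    per-sample quality score.
    """
    rng_gene = np.random.default_rng([gene_seed if gene_seed is not None
                                      else seed, 17])
    rng = np.random.default_rng([seed, 29])
    n, g = design.n_samples, design.n_genes
    cluster = _planted_clusters(design)
    baseline = _gene_baseline(design, rng_gene)
    batch_shift = rng_gene.normal(0.0, design.batch_shift_logsd, size=g)
    phi = rng_gene.lognormal(design.dispersion_logmean,
                             design.dispersion_logsd, size=g)

    grades = rng.choice(["LMP", "NST", "VI"], size=n, p=design.grade_probs)
    score = np.where(grades == "VI", 1.0,
                     np.where(grades == "NST", design.nst_attenuation, 0.0))
    batch = rng.choice(["siteA", "siteB"], size=n)
    lib = rng.lognormal(design.libsize_logmean, design.libsize_logsd, size=n)
    cohort_shift = (rng.normal(0.0, cohort_shift_logsd, size=g)
                    if cohort_shift_logsd > 0 else np.zeros(g))

    log_mu = (np.log(baseline)[:, None]
              + np.log(lib)[None, :]
              + np.log(2.0) * _module_log2_shift(design, cluster, score, rng)
              + np.log(2.0) * np.outer(batch_shift, (batch == "siteB"))
              + np.log(2.0) * cohort_shift[:, None])
    counts = _nb_counts(rng, np.exp(log_mu), phi)

    vi = grades == "VI"
    li_prob = np.where(vi, design.li_given_vi, design.li_given_novi)
    li = rng.random(n) < li_prob
    quality = rng.normal(70.0, 3.0, size=n)

    sample_ids = [f"{sample_prefix}{i + 1:03d}" for i in range(n)]
    counts = pd.DataFrame(counts, index=cluster.index, columns=sample_ids)
    samples = pd.DataFrame({
        "grade": grades,
        "vi": vi.astype(int),
        "li": li.astype(int),
        "batch": batch,
        "quality": quality,
    }, index=pd.Index(sample_ids, name="sample"))
    truth = GroundTruth(
        gene_cluster=cluster[cluster > 0],
        sample_score=pd.Series(score, index=sample_ids, name="latent_score"),
    )
    return counts, samples, truth


# ---------------------------------------------------------------------------
# spatial grids
# ---------------------------------------------------------------------------

@dataclass
class RegionSpec:
    """One painted pathology region: a rectangle or a disc, in spot units."""

    label: str
    shape: str                     # "rect" or "disc"
    params: Tuple[float, ...]      # rect: (x0, y0, x1, y1); disc: (cx, cy, r)

    def contains(self, ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
        if self.shape == "rect":
            x0, y0, x1, y1 = self.params
            return (ix >= x0) & (ix <= x1) & (iy >= y0) & (iy <= y1)
        if self.shape == "disc":
            cx, cy, r = self.params
            return (ix - cx) ** 2 + (iy - cy) ** 2 <= r ** 2
        raise ValueError(f"unknown region shape {self.shape!r}")


#: per-region planted module activity, as per-cluster log2 shifts.
#: VI foci carry the strongest cluster-1/3 elevation and cluster-4 suppression.
_REGION_PROFILES: Dict[str, Tuple[float, float, float, float]] = {
    "normal_lung": (0.0, 0.0, 0.0, 0.6),
    "stroma": (0.0, 0.5, 0.0, 0.3),
    "desmoplastic_stroma": (0.2, 1.5, 0.2, -0.8),
    "lepidic": (0.2, 0.0, 0.2, 0.4),
    "papillary": (0.3, 0.1, 0.3, 0.2),
    "acinar": (0.4, 0.2, 0.4, 0.0),
    "solid": (1.0, 0.3, 1.0, -0.8),
    "cribriform": (0.8, 0.3, 0.8, -0.6),
    "micropapillary": (0.8, 0.2, 0.8, -0.6),
    "vi_focus": (1.5, 0.8, 1.8, -1.5),
    "unannotated": (0.0, 0.0, 0.0, 0.0),
}


def default_layout(nx: int = 24, ny: int = 24) -> List[RegionSpec]:
    """A compact section layout with the annotation classes used in tests."""
    return [
        RegionSpec("normal_lung", "rect", (0, 0, nx - 1, ny - 1)),
        RegionSpec("lepidic", "rect", (1, 1, nx // 2 - 1, ny - 2)),
        RegionSpec("stroma", "rect", (nx // 2, 1, nx - 2, ny // 3)),
        RegionSpec("desmoplastic_stroma", "rect",
                   (nx // 2, ny // 3 + 1, nx - 2, ny // 2)),
        RegionSpec("solid", "rect", (nx // 2, ny // 2 + 1, nx - 2, ny - 2)),
        RegionSpec("vi_focus", "disc", (3 * nx // 4, 3 * ny // 4, 1.5)),
    ]


#: section-wide per-cluster log2 shift carried by VI-positive samples, on top
#: of the regional profiles — the tumor-level angioinvasive phenotype that
#: makes the signature detectable away from the invaded focus.
VI_BACKGROUND_LOG2 = (0.5, 0.3, 0.5, -0.5)


def generate_spot_grid(design: SimDesign, layout: Optional[List[RegionSpec]] = None,
                       seed: int = 0, nx: int = 24, ny: int = 24,
                       sample_id: str = "S1", vi_scale: float = 1.0,
                       background: Optional[Tuple[float, float, float, float]] = None):
    """Simulate one Visium-like capture area on a square lattice.

    Regions are painted in order; where paints overlap the later one wins.
    Per-spot expression is the gene baseline shifted by the spot's region
    profile (a per-cluster log2 shift scaled by ``vi_scale``), sampled as NB
    counts at a log-normal spot depth.  ``background`` adds a section-wide
    per-cluster log2 shift to every spot (use :data:`VI_BACKGROUND_LOG2` for
    a VI-positive sample), so the planted phenotype extends beyond the
    invaded focus.  Returns ``(grid, truth)``.
    """
    rng = np.random.default_rng(seed)
    if layout is None:
        layout = default_layout(nx, ny)
    cluster = _planted_clusters(design)
    baseline = _gene_baseline(design, rng)

    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ix, iy = ix.ravel(), iy.ravel()
    labels = np.array(["unannotated"] * ix.size, dtype=object)
    painted = np.zeros(ix.size, dtype=bool)
    for region in layout:
        mask = region.contains(ix, iy)
        overlap = int((mask & painted).sum())
        if overlap:
            logging.getLogger("visig").warning(
                "region %s overpaints %d spot(s); later paint wins",
                region.label, overlap)
        labels[mask] = region.label
        painted |= mask

    unknown = set(labels) - set(_REGION_PROFILES)
    if unknown:
        raise ValueError(f"no expression profile for region label(s): "
                         f"{sorted(unknown)}")

    # per-spot per-cluster log2 shift from the region profile
    n_spots = ix.size
    shift = np.zeros((design.n_genes, n_spots))
    cl = cluster.to_numpy()
    bg = (0.0, 0.0, 0.0, 0.0) if background is None else tuple(background)
    for label in set(labels):
        profile = _REGION_PROFILES[label]
        mask = labels == label
        for c in range(1, 5):
            shift[np.ix_(cl == c, mask)] = (profile[c - 1] * vi_scale
                                            + bg[c - 1])

    depth = rng.lognormal(design.spot_libsize_logmean,
                          design.spot_libsize_logsd, size=n_spots)
    rel = baseline[:, None] * 2.0 ** shift
    rel = rel / rel.sum(axis=0, keepdims=True)
    mu = rel * depth[None, :]
    phi = rng.lognormal(design.dispersion_logmean, design.dispersion_logsd,
                        size=design.n_genes)
    counts = _nb_counts(rng, mu, phi)

    spot_ids = [f"{sample_id}_spot{i + 1:04d}" for i in range(n_spots)]
    positions = pd.DataFrame({
        "x_um": ix * design.spot_pitch_um,
        "y_um": iy * design.spot_pitch_um,
        "sample_id": sample_id,
    }, index=pd.Index(spot_ids, name="spot_id"))
    grid = SpotGrid(
        counts=pd.DataFrame(counts, index=cluster.index, columns=spot_ids),
        positions=positions,
        labels=pd.Series(labels, index=spot_ids, name="label"),
        pitch_um=design.spot_pitch_um,
    )
    truth = GroundTruth(gene_cluster=cluster[cluster > 0],
                        region_labels=grid.labels.copy())
    return grid, truth


# ---------------------------------------------------------------------------
# multi-region tumors
# ---------------------------------------------------------------------------

def generate_multiregion(design: SimDesign, n_tumors: int = 63,
                         regions_per_tumor: int = 2, seed: int = 0,
                         gene_seed: Optional[int] = None):
    """Simulate multi-region tumors sharing a per-tumor latent score.

    Each tumor draws a latent score in [0, 1]; each region expresses the
    planted modules at ``tumor latent + Normal(0, region_noise_sd)``.
    ``gene_seed`` keys the gene-level stream as in
    :func:`generate_bulk_cohort`, so the regions measure the same genes as a
    matching bulk cohort.  Returns ``(counts, samples, truth)`` with tumor
    and region IDs in ``samples``.
    """
    if regions_per_tumor < 2:
        raise ValueError("regions_per_tumor must be >= 2")
    rng_gene = np.random.default_rng([gene_seed if gene_seed is not None
                                      else seed, 17])
    rng = np.random.default_rng([seed, 29])
    cluster = _planted_clusters(design)
    baseline = _gene_baseline(design, rng_gene)
    g = design.n_genes
    n_regions = n_tumors * regions_per_tumor
    phi = rng_gene.lognormal(design.dispersion_logmean,
                             design.dispersion_logsd, size=g)

    tumor_score = rng.uniform(0.0, 1.0, size=n_tumors)
    region_score = (np.repeat(tumor_score, regions_per_tumor)
                    + rng.normal(0.0, design.region_noise_sd, size=n_regions))
    lib = rng.lognormal(design.libsize_logmean, design.libsize_logsd,
                        size=n_regions)
    log_mu = (np.log(baseline)[:, None] + np.log(lib)[None, :]
              + np.log(2.0) * _module_log2_shift(design, cluster, region_score))
    counts = _nb_counts(rng, np.exp(log_mu), phi)

    tumor_ids = [f"T{i + 1:03d}" for i in range(n_tumors)]
    region_ids = [f"{t}_R{r + 1}" for t in tumor_ids
                  for r in range(regions_per_tumor)]
    counts = pd.DataFrame(counts, index=cluster.index, columns=region_ids)
    samples = pd.DataFrame({
        "tumor_id": np.repeat(tumor_ids, regions_per_tumor),
        "region_id": region_ids,
    }, index=pd.Index(region_ids, name="sample"))
    truth = GroundTruth(
        gene_cluster=cluster[cluster > 0],
        sample_score=pd.Series(region_score, index=region_ids,
                               name="latent_score"),
        tumor_score=pd.Series(tumor_score, index=tumor_ids,
                              name="tumor_score"),
    )
    return counts, samples, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def generate_survival(scores: pd.Series, beta: float, censor_rate: float = 0.3,
                      seed: int = 0, baseline_hazard: float = 0.01) -> pd.DataFrame:
    """Proportional-hazards event times with independent uniform censoring.

    Event times are exponential with hazard ``baseline_hazard * exp(beta *
    score)``.  Censoring times are U(0, tau) with tau solved by bisection on
    the realized event times so the expected censored fraction equals
    ``censor_rate``.  Returns a table with columns ``time`` (months) and
    ``event``.
    """
    values = scores.to_numpy(float)
    if not np.isfinite(values).all():
        raise ValueError("scores must be finite")
    if not (0.0 <= censor_rate <= 1.0):
        raise ValueError("censor_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    hazard = baseline_hazard * np.exp(beta * values)
    t_event = rng.exponential(1.0 / hazard)

    if censor_rate == 0:
        time, event = t_event, np.ones(len(values), dtype=int)
    elif censor_rate == 1:
        time = rng.uniform(0.0, np.maximum(t_event, 1e-12))
        event = np.zeros(len(values), dtype=int)
    else:
        # P(censored | tau) = E[min(T, tau)] / tau for C ~ U(0, tau)
        def censored_frac(tau: float) -> float:
            return float(np.minimum(t_event, tau).mean() / tau)

        lo, hi = 1e-9, float(t_event.max()) * 10 + 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if censored_frac(mid) > censor_rate:
                lo = mid
            else:
                hi = mid
        tau = 0.5 * (lo + hi)
        c = rng.uniform(0.0, tau, size=len(values))
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)

    time = np.maximum(time, 1e-9)
    return pd.DataFrame({"time": time, "event": event}, index=scores.index)
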