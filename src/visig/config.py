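"""Pipeline configuration and deterministic seed plumbing.

A single :class:`PipelineConfig` carries every protocol constant used by the
pipeline: the differential-expression FDR cutoff, the number of signature
clusters, the predictor panel size, the nested cross-validation geometry, the
spot-level QC floor, the spatial bandwidth, and so on.  Defaults encode the
published protocol; all of them are overridable.

Randomized stages never share a NumPy generator.  Each stage derives its own
substream from the global seed via :func:`stage_seed`, so any stage can be
re-run in isolation and reproduce its in-pipeline output exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "stage_seed"]


@dataclass
class PipelineConfig:
    """Protocol constants for the vascular-invasion signature pipeline.

    Attributes
    ----------
    fdr_threshold:
        BH-adjusted significance cutoff for the differential-expression stage.
    n_clusters:
        Number of hierarchical co-expression clusters cut from the signature.
    panel_size:
        Size of the predictor gene panel selected cluster-proportionally.
    outer_iters, outer_train_frac, inner_folds:
        Nested cross-validation geometry: ``outer_iters`` stratified
        train/test splits at ``outer_train_frac``, with ``inner_folds``-fold
        inner CV for the ridge-penalty search.
    n_boot_auroc:
        Bootstrap replicates for the AUROC confidence interval.
    min_genes_per_spot:
        Spot-level QC floor on detected (non-zero) genes.
    region_downsample:
        Pathology regions with fewer annotated spots are dropped; the rest are
        downsampled to this many spots before mixed-model association.
    distance_threshold_um:
        Proximal/distal cutoff (µm) for distance binning around invaded foci.
    bandwidth_spots:
        Kernel bandwidth for spatially weighted correlation, in spot-pitch
        units.
    gsea_weight, gsea_nperm:
        Enrichment-score weighting exponent and permutation count.
    cpm_threshold, cpm_frac:
        Gene filter: keep genes with CPM > ``cpm_threshold`` in at least
        ``ceil(cpm_frac * n_samples)`` samples.
    quality_sd_threshold:
        Samples whose quality score deviates from the cohort mean by more than
        this many SDs are excluded.
    top_n_markers:
        Marker genes retained per cell type for spatial correlation panels.
    celltype_presence_frac:
        Cell types must have at least one predicted cell in this fraction of
        capture areas to be analyzed.
    global_seed:
        Root seed; every randomized stage derives a substream from it.
    """

    fdr_threshold: float = 0.01
    n_clusters: int = 4
    panel_size: int = 48
    outer_iters: int = 100
    outer_train_frac: float = 0.70
    inner_folds: int = 5
    n_boot_auroc: int = 2000
    min_genes_per_spot: int = 250
    region_downsample: int = 200
    distance_threshold_um: float = 1000.0
    bandwidth_spots: float = 5.0
    gsea_weight: float = 1.0
    gsea_nperm: int = 1000
    cpm_threshold: float = 1.0
    cpm_frac: float = 0.10
    quality_sd_threshold: float = 2.0
    top_n_markers: int = 50
    celltype_presence_frac: float = 0.20
    global_seed: int = 0

    _COUNT_FIELDS = (
        "n_clusters",
        "panel_size",
        "outer_iters",
        "inner_folds",
        "n_boot_auroc",
        "min_genes_per_spot",
        "region_downsample",
        "gsea_nperm",
        "top_n_markers",
    )
    _PROPORTION_FIELDS = ("fdr_threshold", "outer_train_frac", "cpm_frac",
                          "celltype_presence_frac")
    _POSITIVE_FIELDS = ("distance_threshold_um", "bandwidth_spots",
                        "cpm_threshold", "quality_sd_threshold")

    def __post_init__(self) -> None:
        for name in self._COUNT_FIELDS:
            value = getattr(self, name)
            if not (isinstance(value, (int,)) and value >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
        for name in self._PROPORTION_FIELDS:
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {value!r}")
        for name in self._POSITIVE_FIELDS:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if not f.name.startswith("_")}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed below 2**31.

    The substream is a deterministic hash of the stage name XOR-mixed with the
    global seed, so renaming a stage changes only that stage's stream and two
    pipelines with equal global seeds agree stage by stage.
    """
    if not isinstance(global_seed, int) or global_seed < 0:
        raise ValueError("global_seed must be a non-negative integer")
    return (zlib.crc32(stage.encode("utf-8")) ^ global_seed) % (2**31)
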