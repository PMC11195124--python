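"""Readers and writers for the formats the pipeline touches.

Counts travel as gene × sample (or gene × spot) integer matrices, either as a
TSV with gene identifiers in the first column, or as a MatrixMarket triplet
accompanied by ``<stem>.genes.txt`` / ``<stem>.samples.txt`` name files.
Spot-level data are a positions TSV (spot_id, x_um, y_um, sample_id), a counts
matrix, and an optional annotation TSV; gene sets use standard GMT.

Everywhere in the package genes are rows and samples/spots are columns, and
identifiers are opaque strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("visig")

__all__ = [
    "SpotGrid",
    "read_count_matrix",
    "write_count_matrix",
    "read_spot_grid",
    "concat_grids",
    "write_spot_grid",
    "read_gene_sets",
    "write_gene_sets",
]


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def _check_unique(values, what: str) -> None:
    index = pd.Index(values)
    if index.has_duplicates:
        dupes = sorted(set(index[index.duplicated()]))
        raise ValueError(f"duplicate {what} identifiers: {dupes}")


def _check_counts(frame: pd.DataFrame) -> pd.DataFrame:
    values = frame.to_numpy()
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"non-finite count at gene {frame.index[bad[0]]!r}, "
                         f"column {frame.columns[bad[1]]!r}")
    if (values < 0).any():
        bad = np.argwhere(values < 0)[0]
        raise ValueError(f"negative count at gene {frame.index[bad[0]]!r}, "
                         f"column {frame.columns[bad[1]]!r}")
    if not np.allclose(values, np.round(values)):
        bad = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValueError(f"non-integer count at gene {frame.index[bad[0]]!r}, "
                         f"column {frame.columns[bad[1]]!r}")
    return frame.astype(np.int64)


def read_count_matrix(path, format: str = "tsv") -> pd.DataFrame:
    """Read a gene × sample count matrix.

    ``format='tsv'`` expects gene IDs in the first column and sample IDs in
    the header.  ``format='mtx-triplet'`` expects ``path`` to point at the
    ``.mtx`` file, with row and column names in sibling ``<stem>.genes.txt``
    and ``<stem>.samples.txt`` files (one identifier per line).
    """
    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
    elif format == "mtx-triplet":
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        matrix = scipy.io.mmread(path)
        if scipy.sparse.issparse(matrix):
            matrix = matrix.toarray()
        frame = pd.DataFrame(np.asarray(matrix), index=genes, columns=samples)
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")
    frame.index.name = None
    _check_unique(frame.index, "gene")
    _check_unique(frame.columns, "sample")
    return _check_counts(frame)


def write_count_matrix(counts: pd.DataFrame, path, format: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        counts.to_csv(path, sep="\t", index_label="gene")
    elif format == "mtx-triplet":
        stem = path.with_suffix("")
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(counts.to_numpy()))
        Path(f"{stem}.genes.txt").write_text("\n".join(counts.index) + "\n")
        Path(f"{stem}.samples.txt").write_text("\n".join(counts.columns) + "\n")
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")


# ---------------------------------------------------------------------------
# spot grids
# ---------------------------------------------------------------------------

@dataclass
class SpotGrid:
    """Spot-level spatial dataset on a regular lattice.

    Attributes
    ----------
    counts:
        gene × spot integer counts.
    positions:
        per-spot table indexed by spot ID with columns ``x_um``, ``y_um`` and
        ``sample_id``.
    labels:
        per-spot pathology annotation; ``"unannotated"`` where absent.
    proportions:
        optional spot × cell-type proportion table (rows sum to 1).
    pitch_um:
        center-to-center lattice spacing in µm.
    """

    counts: pd.DataFrame
    positions: pd.DataFrame
    labels: pd.Series
    proportions: Optional[pd.DataFrame] = None
    pitch_um: float = 100.0

    def __post_init__(self) -> None:
        spots = self.counts.columns
        if not spots.equals(self.positions.index):
            missing = spots.difference(self.positions.index)
            raise ValueError(
                f"{len(missing)} spot(s) in counts missing from positions")
        coords = self.positions[["x_um", "y_um"]].to_numpy(float)
        if not np.isfinite(coords).all():
            raise ValueError("non-finite spot coordinates")
        self.labels = self.labels.reindex(spots).fillna("unannotated")
        if self.proportions is not None:
            props = self.proportions.reindex(spots)
            values = props.to_numpy(float)
            if ((values < -1e-9) | (values > 1 + 1e-9)).any():
                raise ValueError("cell-type proportions outside [0, 1]")
            if not np.allclose(values.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("cell-type proportions must sum to 1 per spot")
            self.proportions = props

    @property
    def spot_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> pd.Series:
        return self.positions["sample_id"]

    @property
    def coords(self) -> np.ndarray:
        return self.positions[["x_um", "y_um"]].to_numpy(float)

    def subset(self, spot_ids) -> "SpotGrid":
        spot_ids = pd.Index(spot_ids)
        return SpotGrid(
            counts=self.counts.loc[:, spot_ids],
            positions=self.positions.loc[spot_ids],
            labels=self.labels.loc[spot_ids],
            proportions=None if self.proportions is None
            else self.proportions.loc[spot_ids],
            pitch_um=self.pitch_um,
        )


def concat_grids(grids) -> "SpotGrid":
    """Concatenate single-sample grids into one multi-sample :class:`SpotGrid`.

    Requires identical gene panels and a shared lattice pitch; spot IDs must
    be globally unique across the inputs.
    """
    grids = list(grids)
    if not grids:
        raise ValueError("no grids to concatenate")
    genes = grids[0].counts.index
    pitch = grids[0].pitch_um
    for grid in grids[1:]:
        if not grid.counts.index.equals(genes):
            raise ValueError("grids have different gene panels")
        if grid.pitch_um != pitch:
            raise ValueError("grids have different lattice pitches")
    counts = pd.concat([g.counts for g in grids], axis=1)
    positions = pd.concat([g.positions for g in grids], axis=0)
    labels = pd.concat([g.labels for g in grids], axis=0)
    props = None
    if all(g.proportions is not None for g in grids):
        props = pd.concat([g.proportions for g in grids], axis=0)
    return SpotGrid(counts=counts, positions=positions, labels=labels,
                    proportions=props, pitch_um=pitch)


def read_spot_grid(counts_path, positions_path, annotations_path=None,
                   counts_format: str = "tsv", pitch_um: float = 100.0) -> SpotGrid:
    """Assemble a :class:`SpotGrid` from its on-disk trio.

    Spots present in the counts but absent from the positions table are an
    error (the unmatched count is reported); spots without an annotation row
    default to ``"unannotated"``.
    """
    counts = read_count_matrix(counts_path, format=counts_format)
    positions = pd.read_csv(positions_path, sep="\t", index_col=0)
    positions.index = positions.index.astype(str)
    if "sample_id" not in positions.columns:
        positions = positions.assign(sample_id="S1")
    unmatched = counts.columns.difference(positions.index)
    if len(unmatched):
        raise ValueError(
            f"{len(unmatched)} spot ID(s) in counts have no position entry")
    positions = positions.loc[counts.columns]
    if annotations_path is None:
        labels = pd.Series("unannotated", index=counts.columns)
    else:
        annot = pd.read_csv(annotations_path, sep="\t", index_col=0)
        annot.index = annot.index.astype(str)
        labels = annot.iloc[:, 0].reindex(counts.columns).fillna("unannotated")
    labels = labels.astype(str)
    return SpotGrid(counts=counts, positions=positions, labels=labels,
                    pitch_um=pitch_um)


def write_spot_grid(grid: SpotGrid, counts_path, positions_path,
                    annotations_path, counts_format: str = "tsv") -> None:
    write_count_matrix(grid.counts, counts_path, format=counts_format)
    grid.positions.to_csv(positions_path, sep="\t", index_label="spot_id")
    grid.labels.rename("label").to_frame().to_csv(
        annotations_path, sep="\t", index_label="spot_id")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Ordered name → gene-list mapping with optional per-set descriptions."""

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if any(not g for g in genes):
                raise ValueError(f"gene set {name!r} has empty identifiers")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then tab-separated gene IDs.

    Duplicate genes within a set are dropped (first occurrence kept) with a
    logged warning; a line with fewer than three fields is an error.
    """
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, description, *genes = parts
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning("gene set %s: %d duplicate gene(s) dropped",
                               name, len(genes) - len(unique))
            sets[name] = unique
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    lines = []
    for name, genes in collection.items():
        description = collection.descriptions.get(name, "")
        lines.append("\t".join([name, description, *genes]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
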