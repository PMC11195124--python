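import numpy as np
import pandas as pd
import pytest

from visig import (SimDesign, celltype_presence_filter, concat_grids,
                   distance_bins, generate_spot_grid, highgrade_vi_contrast,
                   lognormalize_spots, region_association, spot_qc,
                   weighted_local_correlation)
from visig.io import SpotGrid


def _tiny_grid(n=5, n_genes=6, seed=0, pitch=100.0, sample_id="S1"):
    rng = np.random.default_rng(seed)
    spots = [f"{sample_id}_sp{i}" for i in range(n * n)]
    ix, iy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    counts = pd.DataFrame(rng.integers(0, 50, size=(n_genes, n * n)),
                          index=[f"g{i}" for i in range(n_genes)],
                          columns=spots)
    positions = pd.DataFrame({"x_um": ix.ravel() * pitch,
                              "y_um": iy.ravel() * pitch,
                              "sample_id": sample_id},
                             index=pd.Index(spots, name="spot_id"))
    labels = pd.Series("unannotated", index=spots)
    return SpotGrid(counts=counts, positions=positions, labels=labels,
                    pitch_um=pitch)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def test_spot_qc_boundary_at_exact_threshold():
    grid = _tiny_grid(n=2, n_genes=300)
    counts = grid.counts.copy()
    counts.iloc[:, :] = 1
    counts.iloc[249:, 0] = 0   # spot 0: 249 detected genes -> removed
    counts.iloc[250:, 1] = 0   # spot 1: 250 detected genes -> retained
    grid = SpotGrid(counts=counts, positions=grid.positions,
                    labels=grid.labels, pitch_um=grid.pitch_um)
    out = spot_qc(grid, min_genes=250)
    assert grid.spot_ids[0] not in out.spot_ids
    assert grid.spot_ids[1] in out.spot_ids
    # everything above threshold: identity
    full = spot_qc(out, min_genes=1)
    assert list(full.spot_ids) == list(out.spot_ids)


def test_spot_qc_matches_brute_force_on_synthetic_grid():
    design = SimDesign(n_genes=400)
    grid, _ = generate_spot_grid(design, seed=2, nx=8, ny=8)
    detected = (grid.counts > 0).sum(axis=0)
    expected = set(detected.index[detected >= 150])
    out = spot_qc(grid, min_genes=150)
    assert set(out.spot_ids) == expected


def test_lognormalize_depth_invariance_and_formula():
    grid = _tiny_grid(seed=3)
    norm = lognormalize_spots(grid, scale_target=1e4)
    x = grid.counts.to_numpy(float)
    expected = np.log1p(x / x.sum(axis=0) * 1e4)
    np.testing.assert_allclose(norm.to_numpy(), expected, atol=1e-12)
    # doubling a spot's counts changes nothing
    doubled = grid.counts.copy()
    doubled.iloc[:, 0] *= 2
    grid2 = SpotGrid(counts=doubled, positions=grid.positions,
                     labels=grid.labels, pitch_um=grid.pitch_um)
    norm2 = lognormalize_spots(grid2, scale_target=1e4)
    np.testing.assert_allclose(norm2.iloc[:, 0], norm.iloc[:, 0], atol=1e-12)
    # single expressed gene gets log1p(scale_target)
    single = grid.counts.copy()
    single.iloc[:, 1] = 0
    single.iloc[2, 1] = 7
    grid3 = SpotGrid(counts=single, positions=grid.positions,
                     labels=grid.labels, pitch_um=grid.pitch_um)
    norm3 = lognormalize_spots(grid3, scale_target=1e4)
    assert norm3.iloc[2, 1] == pytest.approx(np.log1p(1e4))


# ---------------------------------------------------------------------------
# weighted local correlation
# ---------------------------------------------------------------------------

def test_local_correlation_of_identical_maps_is_one():
    grid = _tiny_grid(seed=4)
    scores = pd.Series(np.random.default_rng(0).normal(size=grid.n_spots),
                       index=grid.spot_ids)
    res = weighted_local_correlation(grid, scores, scores, bandwidth=2,
                                     rank_transform=False)
    valid = res.values.dropna()
    np.testing.assert_allclose(valid, 1.0, atol=1e-10)


def test_local_correlation_large_bandwidth_equals_global():
    grid = _tiny_grid(seed=5)
    rng = np.random.default_rng(1)
    a = pd.Series(rng.normal(size=grid.n_spots), index=grid.spot_ids)
    b = pd.Series(rng.normal(size=grid.n_spots), index=grid.spot_ids)
    res = weighted_local_correlation(grid, a, b, bandwidth=1e9,
                                     kernel="gaussian", rank_transform=False)
    global_r = np.corrcoef(a, b)[0, 1]
    np.testing.assert_allclose(res.values.dropna(), global_r, atol=1e-6)


def test_local_correlation_matches_brute_force_loop():
    grid = _tiny_grid(n=5, seed=6)
    rng = np.random.default_rng(2)
    a = pd.Series(rng.normal(size=25), index=grid.spot_ids)
    b = pd.Series(rng.normal(size=25), index=grid.spot_ids)
    res = weighted_local_correlation(grid, a, b, bandwidth=2,
                                     kernel="bisquare", rank_transform=False)
    coords = grid.coords
    h = 2 * grid.pitch_um
    for i in range(25):
        d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
        w = np.where(d / h < 1, (1 - (d / h) ** 2) ** 2, 0.0)
        if (w > 0).sum() < 3:
            assert np.isnan(res.values.iloc[i])
            continue
        aw = np.sum(w * a) / np.sum(w)
        bw = np.sum(w * b) / np.sum(w)
        cov = np.sum(w * (a - aw) * (b - bw)) / np.sum(w)
        va = np.sum(w * (a - aw) ** 2) / np.sum(w)
        vb = np.sum(w * (b - bw) ** 2) / np.sum(w)
        np.testing.assert_allclose(res.values.iloc[i], cov / np.sqrt(va * vb),
                                   atol=1e-12)


# ---------------------------------------------------------------------------
# region association
# ---------------------------------------------------------------------------

def _painted_cohort(n_samples=4, shift=0.0, seed=0, nx=12, ny=12):
    """Multi-sample grids with a two-region paint and an optional planted shift."""
    rng = np.random.default_rng(seed)
    grids, values = [], []
    for s in range(n_samples):
        grid = _tiny_grid(n=nx, seed=seed + s, sample_id=f"S{s}")
        labels = np.where(np.arange(grid.n_spots) % 2 == 0,
                          "normal_lung", "tumor")
        grid = SpotGrid(counts=grid.counts, positions=grid.positions,
                        labels=pd.Series(labels, index=grid.spot_ids),
                        pitch_um=grid.pitch_um)
        value = rng.normal(0, 1, grid.n_spots) + rng.normal(0, 0.3)
        value[labels == "tumor"] += shift
        grids.append(grid)
        values.append(pd.Series(value, index=grid.spot_ids))
    return concat_grids(grids), pd.concat(values)


def test_region_association_null_is_calibrated_and_planted_shift_found():
    grid, values = _painted_cohort(shift=0.0, seed=1)
    res0 = region_association(grid, values, downsample_n=60, seed=0)
    assert res0.at["tumor", "pvalue"] > 0.001
    grid2, values2 = _painted_cohort(shift=2.0, seed=2)
    res2 = region_association(grid2, values2, downsample_n=60, seed=0)
    assert res2.at["tumor", "estimate"] > 1.0
    assert res2.at["tumor", "padj"] < 0.01


def test_region_association_constant_values_give_null_result():
    grid, values = _painted_cohort(seed=3)
    res = region_association(grid, values * 0.0, downsample_n=60, seed=0)
    assert (res["estimate"] == 0).all()
    assert (res["padj"] == 1).all()


def test_region_association_drops_small_labels():
    grid, values = _painted_cohort(seed=4)
    labels = grid.labels.copy()
    labels.iloc[:10] = "rare"   # 10 spots < downsample_n
    grid = SpotGrid(counts=grid.counts, positions=grid.positions,
                    labels=labels, pitch_um=grid.pitch_um)
    res = region_association(grid, values, downsample_n=60, seed=0)
    assert "rare" not in res.index


def test_region_association_without_downsampling_is_deterministic():
    grid, values = _painted_cohort(shift=1.0, seed=5)
    r1 = region_association(grid, values, downsample_n=None, seed=1)
    r2 = region_association(grid, values, downsample_n=None, seed=99)
    pd.testing.assert_frame_equal(r1, r2)


def test_region_association_missing_reference_errors():
    grid, values = _painted_cohort(seed=6)
    with pytest.raises(ValueError, match="reference"):
        region_association(grid, values, reference_label="nope",
                           downsample_n=60, seed=0)


# ---------------------------------------------------------------------------
# high-grade contrast
# ---------------------------------------------------------------------------

def _highgrade_samples(shift, seed, n_samples=6):
    rng = np.random.default_rng(seed)
    grids, scores, status = [], [], {}
    for s in range(n_samples):
        grid = _tiny_grid(n=8, seed=seed + s, sample_id=f"S{s}")
        labels = np.where(np.arange(grid.n_spots) % 3 == 0, "solid",
                          np.where(np.arange(grid.n_spots) % 3 == 1,
                                   "cribriform", "lepidic"))
        grid = SpotGrid(counts=grid.counts, positions=grid.positions,
                        labels=pd.Series(labels, index=grid.spot_ids),
                        pitch_um=grid.pitch_um)
        vi = int(s % 2 == 0)
        status[f"S{s}"] = vi
        value = rng.normal(0, 1, grid.n_spots) + rng.normal(0, 0.2)
        if vi:
            value[np.isin(labels, ["solid", "cribriform"])] += shift
        grids.append(grid)
        scores.append(pd.Series(value, index=grid.spot_ids))
    return grids, scores, status


def test_highgrade_contrast_recovers_planted_shift():
    grids, scores, status = _highgrade_samples(shift=1.0, seed=10)
    est, p = highgrade_vi_contrast(grids, scores, status)
    assert est > 0.5
    assert p < 0.01


def test_highgrade_contrast_null_not_systematically_significant():
    hits = 0
    for rep in range(10):
        grids, scores, status = _highgrade_samples(shift=0.0, seed=100 + rep)
        _, p = highgrade_vi_contrast(grids, scores, status)
        if p < 0.001:
            hits += 1
    assert hits == 0


def test_highgrade_contrast_empty_stratum_errors():
    grids, scores, status = _highgrade_samples(shift=0.0, seed=20)
    with pytest.raises(ValueError, match="empty stratum"):
        highgrade_vi_contrast(grids, scores, status,
                              highgrade_labels=["micropapillary"])


# ---------------------------------------------------------------------------
# distance binning
# ---------------------------------------------------------------------------

def test_distance_bins_rules():
    grid = _tiny_grid(n=15, pitch=100.0)   # 15x15, 100 µm pitch
    labels = grid.labels.copy()
    labels.iloc[0] = "vi_focus"            # spot at (0, 0)
    grid = SpotGrid(counts=grid.counts, positions=grid.positions,
                    labels=labels, pitch_um=grid.pitch_um)
    bins = distance_bins(grid, "vi_focus", threshold_um=1000.0)
    assert bins.iloc[0] == "proximal"       # the labeled spot itself
    # spot at (1100, 0) µm is 1100 > 1000 away -> distal
    idx_1100 = grid.positions.index[
        (grid.positions.x_um == 1100) & (grid.positions.y_um == 0)][0]
    assert bins[idx_1100] == "distal"
    # spot at (1000, 0) µm: exactly at threshold -> proximal
    idx_1000 = grid.positions.index[
        (grid.positions.x_um == 1000) & (grid.positions.y_um == 0)][0]
    assert bins[idx_1000] == "proximal"


def test_distance_bins_no_focus_means_all_proximal():
    grid = _tiny_grid(n=6)
    bins = distance_bins(grid, "vi_focus", threshold_um=1000.0)
    assert (bins == "proximal").all()


def test_distance_bins_monotone_in_threshold():
    grid = _tiny_grid(n=10)
    labels = grid.labels.copy()
    labels.iloc[37] = "vi_focus"
    grid = SpotGrid(counts=grid.counts, positions=grid.positions,
                    labels=labels, pitch_um=grid.pitch_um)
    lo = distance_bins(grid, "vi_focus", threshold_um=300.0)
    hi = distance_bins(grid, "vi_focus", threshold_um=800.0)
    assert ((lo == "proximal") <= (hi == "proximal")).all()


def test_distance_bins_small_focus_within_1mm_is_proximal():
    design = SimDesign(n_genes=150)
    from visig.simulate import RegionSpec
    layout = [RegionSpec("normal_lung", "rect", (0, 0, 19, 19)),
              RegionSpec("vi_focus", "disc", (10, 10, 1.01))]
    grid, _ = generate_spot_grid(design, layout=layout, seed=0, nx=20, ny=20)
    bins = distance_bins(grid, "vi_focus", threshold_um=1000.0)
    focus_spots = grid.spot_ids[grid.labels == "vi_focus"]
    assert len(focus_spots) >= 3
    assert (bins.loc[focus_spots] == "proximal").all()


# ---------------------------------------------------------------------------
# cell-type presence filter
# ---------------------------------------------------------------------------

def test_celltype_presence_filter_rules():
    counts = pd.DataFrame({
        f"s{j}": [10, 1 if j < 2 else 0, 0] for j in range(15)
    }, index=["everywhere", "two_samples", "nowhere"])
    kept = celltype_presence_filter(counts, presence_frac=0.20)
    # ceil(0.2 * 15) = 3 samples required
    assert list(kept) == ["everywhere"]
    assert len(celltype_presence_filter(counts, presence_frac=0.0)) == 3
    with pytest.raises(ValueError):
        celltype_presence_filter(counts - 20, presence_frac=0.2)
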