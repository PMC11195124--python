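import math

import numpy as np
import pandas as pd
import pytest

from visig import (filter_genes, filter_samples_quality, logcpm,
                   reference_batch_adjust, tmm_factors)
from visig.preprocess import ExprMatrix


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def brute_force_tmm(counts: pd.DataFrame) -> np.ndarray:
    """Naive re-derivation of the TMM definition with explicit loops."""
    x = counts.to_numpy(float)
    lib = x.sum(axis=0)
    f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75)
                    for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = []
    for j in range(x.shape[1]):
        obs, refv = x[:, j], x[:, ref]
        keep = (obs > 0) & (refv > 0)
        o, r = obs[keep], refv[keep]
        m = np.log2((o / lib[j]) / (r / lib[ref]))
        a = 0.5 * np.log2((o / lib[j]) * (r / lib[ref]))
        v = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        if np.allclose(m, 0, atol=1e-10):
            factors.append(1.0)
            continue
        n = len(m)
        lo_m, hi_m = math.floor(n * 0.3) + 1, n - math.floor(n * 0.3)
        lo_a, hi_a = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        sel = ((rank_m >= lo_m) & (rank_m <= hi_m)
               & (rank_a >= lo_a) & (rank_a <= hi_a))
        factors.append(2 ** (np.sum(m[sel] / v[sel]) / np.sum(1 / v[sel])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def test_tmm_identical_columns_give_unit_factors():
    col = np.array([10, 20, 5, 0, 100, 7])
    counts = pd.DataFrame(np.tile(col[:, None], 3),
                          index=list("abcdef"), columns=list("xyz"))
    assert np.allclose(tmm_factors(counts), 1.0)


def test_tmm_pure_depth_difference_gives_unit_factors():
    rng = np.random.default_rng(0)
    a = rng.integers(1, 200, size=40)
    counts = pd.DataFrame({"A": a, "B": 2 * a})
    assert np.allclose(tmm_factors(counts), 1.0)


def test_tmm_matches_brute_force_on_asymmetric_fixture():
    rng = np.random.default_rng(3)
    x = rng.integers(5, 500, size=(20, 4))
    x[:4, 1] *= 8  # 4 genes strongly up in sample 2
    counts = pd.DataFrame(x, index=[f"g{i}" for i in range(20)],
                          columns=list("ABCD"))
    np.testing.assert_allclose(tmm_factors(counts).to_numpy(),
                               brute_force_tmm(counts), atol=1e-10)


def test_tmm_all_zero_sample_errors():
    counts = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
    with pytest.raises(ValueError, match="B"):
        tmm_factors(counts)


# ---------------------------------------------------------------------------
# logCPM
# ---------------------------------------------------------------------------

def test_logcpm_arithmetic_without_prior():
    counts = pd.DataFrame({"A": [5, 5], "B": [5, 5]}, index=["g1", "g2"])
    expr = logcpm(counts, prior_count=1e-12)
    assert np.allclose(expr.values.to_numpy(), np.log2(5e5), atol=1e-6)


def test_logcpm_prior_regularizes_zero_counts():
    counts = pd.DataFrame({"A": [0, 100], "B": [0, 100]}, index=["g0", "g1"])
    with_prior = logcpm(counts, prior_count=2).values.loc["g0"]
    nearly_none = logcpm(counts, prior_count=1e-6).values.loc["g0"]
    assert np.isfinite(with_prior).all()
    assert (with_prior > nearly_none).all()


def test_logcpm_matches_direct_formula():
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(rng.integers(0, 300, size=(50, 6)),
                          index=[f"g{i}" for i in range(50)],
                          columns=[f"s{j}" for j in range(6)])
    factors = tmm_factors(counts)
    expr = logcpm(counts, factors, prior_count=2)
    x = counts.to_numpy(float)
    lib = x.sum(axis=0) * factors.to_numpy()
    prior = 2 * lib / lib.mean()
    expected = np.log2((x + prior) / (lib + 2 * prior) * 1e6)
    np.testing.assert_allclose(expr.values.to_numpy(), expected, atol=1e-12)


def test_logcpm_monotone_within_sample():
    counts = pd.DataFrame({"A": [0, 1, 10, 100]}, index=list("wxyz"))
    counts["B"] = [5, 5, 5, 5]
    col = logcpm(counts).values["A"].to_numpy()
    assert np.all(np.diff(col) > 0)


# ---------------------------------------------------------------------------
# gene / sample filters
# ---------------------------------------------------------------------------

def test_filter_genes_rules_and_boundary():
    # 10 samples; gene passing in exactly 1 sample at frac=0.10 is retained
    counts = pd.DataFrame(np.ones((3, 10), dtype=int) * 100,
                          index=["all", "one", "none"],
                          columns=[f"s{j}" for j in range(10)])
    counts.loc["one"] = 0
    counts.loc["one", "s0"] = 100
    counts.loc["none"] = 0
    kept = filter_genes(counts, cpm_threshold=1, frac=0.10)
    assert list(kept.index) == ["all", "one"]


def test_filter_genes_matches_enumeration_and_is_idempotent():
    rng = np.random.default_rng(9)
    counts = pd.DataFrame(rng.integers(0, 5, size=(100, 12)) * 1000,
                          index=[f"g{i}" for i in range(100)],
                          columns=[f"s{j}" for j in range(12)])
    counts += 1  # avoid zero library sizes
    kept = filter_genes(counts, cpm_threshold=1, frac=0.10)
    cpm = counts / counts.sum(axis=0) * 1e6
    expected = (cpm > 1).sum(axis=1) >= math.ceil(0.10 * 12)
    assert kept.shape[0] == int(expected.sum())
    pd.testing.assert_frame_equal(filter_genes(kept, 1, 0.10), kept)


def test_quality_filter_removes_outlier_and_keeps_identical():
    values = [50.0, 51.0, 49.0, 50.0, 52.0, 48.0, 51.0, 49.0, 50.0, 20.0]
    scores = pd.Series(values, index=[f"s{i}" for i in range(10)])
    mean, sd = scores.mean(), scores.std(ddof=1)
    assert abs(20 - mean) > 2 * sd  # the rule fires by direct computation
    kept = filter_samples_quality(scores, sd_threshold=2.0)
    assert list(kept) == [f"s{i}" for i in range(9)]
    same = pd.Series({"a": 5.0, "b": 5.0, "c": 5.0})
    assert list(filter_samples_quality(same)) == ["a", "b", "c"]
    assert len(filter_samples_quality(scores, sd_threshold=np.inf)) == 10


# ---------------------------------------------------------------------------
# reference-batch adjustment
# ---------------------------------------------------------------------------

def _expr_from_values(values: np.ndarray, samples) -> ExprMatrix:
    frame = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                         columns=samples)
    ones = pd.Series(1.0, index=frame.columns)
    return ExprMatrix(values=frame, lib_size=ones * 1e6, norm_factors=ones)


def test_reference_batch_is_bit_identical_and_identical_batches_unchanged():
    rng = np.random.default_rng(2)
    block = rng.normal(5, 1, size=(30, 4))
    values = np.concatenate([block, block], axis=1)
    samples = [f"r{j}" for j in range(4)] + [f"v{j}" for j in range(4)]
    batches = pd.Series(["ref"] * 4 + ["val"] * 4, index=samples)
    expr = _expr_from_values(values, samples)
    out = reference_batch_adjust(expr, batches, reference="ref", shrink=False)
    # reference contract: bit-identical
    assert (out.values.iloc[:, :4].to_numpy()
            == expr.values.iloc[:, :4].to_numpy()).all()
    # identical batches: adjustment is a no-op
    np.testing.assert_allclose(out.values.to_numpy(), values, atol=1e-8)


def test_reference_batch_removes_constant_location_shift():
    rng = np.random.default_rng(4)
    ref = rng.normal(0, 1, size=(40, 6))
    val = ref[:, :5] + 3.0  # same per-gene shape, +3 shift
    values = np.concatenate([ref, val], axis=1)
    samples = [f"r{j}" for j in range(6)] + [f"v{j}" for j in range(5)]
    batches = pd.Series(["ref"] * 6 + ["val"] * 5, index=samples)
    expr = _expr_from_values(values, samples)
    out = reference_batch_adjust(expr, batches, reference="ref", shrink=False)
    ref_means = out.values.iloc[:, :6].mean(axis=1)
    val_means = out.values.iloc[:, 6:].mean(axis=1)
    np.testing.assert_allclose(val_means, ref_means, atol=1e-8)


def test_reference_batch_standardization_targets_without_shrinkage():
    rng = np.random.default_rng(6)
    values = rng.normal(0, 1, size=(25, 12))
    values[:, 6:] = values[:, 6:] * 2.5 + 1.0
    samples = [f"s{j}" for j in range(12)]
    batches = pd.Series(["A"] * 6 + ["B"] * 6, index=samples)
    expr = _expr_from_values(values, samples)
    out = reference_batch_adjust(expr, batches, reference="A", shrink=False)
    a = out.values.iloc[:, :6].to_numpy()
    b = out.values.iloc[:, 6:].to_numpy()
    np.testing.assert_allclose(b.mean(axis=1), a.mean(axis=1), atol=1e-6)
    np.testing.assert_allclose(b.std(axis=1, ddof=1), a.std(axis=1, ddof=1),
                               atol=1e-6)


def test_reference_batch_single_sample_batch_errors():
    values = np.random.default_rng(0).normal(size=(5, 4))
    samples = list("wxyz")
    batches = pd.Series(["A", "A", "A", "B"], index=samples)
    expr = _expr_from_values(values, samples)
    with pytest.raises(ValueError, match="<2 samples"):
        reference_batch_adjust(expr, batches, reference="A")
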