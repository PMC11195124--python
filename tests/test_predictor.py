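import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from visig import (PipelineConfig, PredictorModel, auroc, feature_importance,
                   nested_cv, predict_scores, select_features,
                   train_ridge_logit)
from visig.predictor import _auroc_point, _ridge_logit_irls, largest_remainder
from visig.signature import SignatureClusters


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def _de_table(p_by_cluster, clusters_of_genes):
    genes = [f"g{i:03d}" for i in range(len(clusters_of_genes))]
    de = pd.DataFrame({
        "PValue": p_by_cluster,
        "logFC": 1.0,
        "FDR": np.asarray(p_by_cluster) * 1.5,
    }, index=genes)
    assignments = pd.Series(clusters_of_genes, index=genes)
    sc = SignatureClusters(assignments=assignments,
                          directions={c: "up" for c in set(clusters_of_genes)})
    return de, sc


def test_largest_remainder_spec_quotas():
    # shares 60/20/10/10 of the significant genes, panel 48 -> 29/9/5/5
    np.testing.assert_array_equal(
        largest_remainder(np.array([0.6, 0.2, 0.1, 0.1]), 48), [29, 9, 5, 5])
    assert largest_remainder(np.array([1.0]), 48).sum() == 48


def test_select_features_proportional_quotas():
    sizes = {1: 60, 2: 20, 3: 10, 4: 10}
    clusters_of_genes = sum(([c] * n for c, n in sizes.items()), [])
    rng = np.random.default_rng(0)
    pvals = rng.uniform(1e-8, 1e-4, len(clusters_of_genes))
    de, sc = _de_table(pvals, clusters_of_genes)
    panel = select_features(de, sc, panel_size=48, fdr_threshold=0.01)
    assert len(panel) == 48
    chosen = sc.assignments.loc[panel].value_counts().sort_index()
    np.testing.assert_array_equal(chosen.to_numpy(), [29, 9, 5, 5])
    # within-cluster ordering is by ascending p-value
    c1 = [g for g in panel if sc.assignments[g] == 1]
    assert (de.loc[c1, "PValue"].diff().dropna() >= 0).all()


def test_select_features_single_cluster_and_exact_panel():
    de, sc = _de_table(np.linspace(1e-8, 1e-4, 60), [1] * 60)
    panel = select_features(de, sc, panel_size=48)
    assert panel == list(de["PValue"].nsmallest(48).index)
    de2, sc2 = _de_table(np.linspace(1e-8, 1e-4, 48),
                         [1] * 20 + [2] * 10 + [3] * 10 + [4] * 8)
    panel2 = select_features(de2, sc2, panel_size=48)
    assert sorted(panel2) == sorted(de2.index)


def test_select_features_too_few_significant_errors():
    de, sc = _de_table(np.linspace(1e-4, 0.5, 30), [1] * 30)
    with pytest.raises(ValueError, match="significant"):
        select_features(de, sc, panel_size=48)


def test_select_features_quota_capped_by_availability():
    # cluster 1 has only 3 significant genes but a large share is impossible
    de, sc = _de_table(np.linspace(1e-8, 1e-6, 52), [1] * 3 + [2] * 49)
    panel = select_features(de, sc, panel_size=50)
    chosen = sc.assignments.loc[panel].value_counts()
    assert chosen[1] == 3 and chosen[2] == 47 and len(panel) == 50


# ---------------------------------------------------------------------------
# ridge logit
# ---------------------------------------------------------------------------

def test_ridge_limit_shrinks_to_prevalence():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(60, 5))
    y = (rng.random(60) < 0.3).astype(float)
    b0, b = _ridge_logit_irls(X, y, lam=1e9)
    assert np.abs(b).max() < 1e-5
    assert 1 / (1 + np.exp(-b0)) == pytest.approx(y.mean(), abs=1e-3)


def test_unpenalized_fit_matches_statsmodels_logit():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(80, 3))
    logits = 0.3 + X @ np.array([0.8, -0.5, 0.2])
    y = (rng.random(80) < 1 / (1 + np.exp(-logits))).astype(float)
    b0, b = _ridge_logit_irls(X, y, lam=0.0)
    oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(np.r_[b0, b], oracle.params, atol=1e-4)


def test_planted_two_gene_signal_recovers_held_out_auroc():
    rng = np.random.default_rng(3)
    n = 200
    y = np.tile([0, 1], n // 2)
    X = rng.normal(size=(n, 10))
    X[:, 0] += 1.5 * y
    X[:, 1] -= 1.5 * y
    expr = pd.DataFrame(X[:100].T, index=[f"g{i}" for i in range(10)],
                        columns=[f"s{j}" for j in range(100)])
    labels = pd.Series(y[:100], index=expr.columns)
    model = train_ridge_logit(expr, labels, seed=0)
    held = pd.DataFrame(X[100:].T, index=expr.index,
                        columns=[f"t{j}" for j in range(100)])
    scores = predict_scores(model, held)
    assert _auroc_point(scores.to_numpy(), y[100:].astype(float)) >= 0.9


def test_predict_scores_contracts():
    genes = ["g1", "g2"]
    model = PredictorModel(
        genes=genes,
        mean=pd.Series([0.0, 0.0], index=genes),
        sd=pd.Series([1.0, 1.0], index=genes),
        intercept=0.5,
        coef=pd.Series([0.0, 0.0], index=genes),
        penalty=1.0,
    )
    expr = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=genes,
                        columns=["a", "b"])
    scores = predict_scores(model, expr)
    np.testing.assert_allclose(scores, 1 / (1 + np.exp(-0.5)), atol=1e-12)
    # hand-computed logistic values for nonzero coefficients
    model2 = PredictorModel(genes=genes, mean=model.mean, sd=model.sd,
                            intercept=-1.0,
                            coef=pd.Series([2.0, -1.0], index=genes),
                            penalty=0.1)
    expected = 1 / (1 + np.exp(-(-1 + 2 * expr.loc["g1"] - expr.loc["g2"])))
    np.testing.assert_allclose(predict_scores(model2, expr), expected,
                               atol=1e-12)
    with pytest.raises(ValueError, match="missing"):
        predict_scores(model, expr.iloc[:1])


def test_model_json_round_trip(tmp_path):
    genes = ["g1", "g2", "g3"]
    model = PredictorModel(
        genes=genes,
        mean=pd.Series([1.0, 2.0, 3.0], index=genes),
        sd=pd.Series([1.0, 0.5, 2.0], index=genes),
        intercept=-0.25,
        coef=pd.Series([0.1, -0.2, 0.3], index=genes),
        penalty=3.2,
        train_auroc=0.9,
    )
    model.to_json(tmp_path / "model.json")
    back = PredictorModel.from_json(tmp_path / "model.json")
    assert back.genes == genes
    np.testing.assert_allclose(back.coef, model.coef)
    assert back.penalty == model.penalty


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def test_auroc_trivial_and_exhaustive_oracle():
    scores = pd.Series([0.9, 0.8, 0.7, 0.3, 0.2, 0.1],
                       index=list("abcdef"))
    labels = pd.Series([1, 1, 1, 0, 0, 0], index=scores.index)
    res = auroc(scores, labels, n_boot=100, seed=0)
    assert res["auroc"] == 1.0

    # 6-sample fixture with a tie: brute-force pair enumeration
    s = pd.Series([0.9, 0.5, 0.5, 0.4, 0.2, 0.1], index=list("abcdef"))
    lab = pd.Series([1, 1, 0, 0, 1, 0], index=s.index)
    pairs = [(i, j) for i in s.index[lab == 1] for j in s.index[lab == 0]]
    oracle = np.mean([1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0
                      for i, j in pairs])
    res2 = auroc(s, lab, n_boot=100, seed=0)
    assert res2["auroc"] == pytest.approx(oracle, abs=1e-12)
    # agreement with the library's implementation on the same fixture
    assert res2["auroc"] == pytest.approx(roc_auc_score(lab, s), abs=1e-12)


def test_auroc_null_and_ci():
    rng = np.random.default_rng(4)
    scores = pd.Series(rng.normal(size=1000))
    labels = pd.Series(rng.integers(0, 2, 1000), index=scores.index)
    res = auroc(scores, labels, n_boot=200, seed=1)
    assert abs(res["auroc"] - 0.5) < 0.05
    assert res["ci_low"] < res["auroc"] < res["ci_high"]
    assert res["wilcoxon_p"] > 0.001


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

def test_nested_cv_determinism_and_schema(bulk_cohort):
    _, counts, samples, _ = bulk_cohort
    cfg = PipelineConfig()
    cv1 = nested_cv(counts, samples, cfg, seed=77, outer_iters=2)
    cv2 = nested_cv(counts, samples, cfg, seed=77, outer_iters=2)
    pd.testing.assert_frame_equal(cv1, cv2)
    assert len(cv1) == 2
    assert (cv1["panel"].str.split(",").str.len() == cfg.panel_size).all()
    n = counts.shape[1]
    assert (cv1["n_train"] + cv1["n_test"] == n).all()


def test_nested_cv_no_leakage_from_test_labels(bulk_cohort, tmp_path):
    """With the split fixed, corrupting held-out labels must not change the
    trained model (byte-identical serialization)."""
    from sklearn.model_selection import train_test_split

    from visig.predictor import run_outer_iteration

    _, counts, samples, _ = bulk_cohort
    cfg = PipelineConfig()
    y = samples.loc[counts.columns, "vi"].astype(int)
    train_ids, test_ids = train_test_split(
        counts.columns.to_numpy(), train_size=cfg.outer_train_frac,
        stratify=y.to_numpy(), random_state=13)
    model1, row1 = run_outer_iteration(counts, samples, train_ids, test_ids,
                                       cfg, seed=13)
    corrupted = samples.copy()
    corrupted.loc[test_ids, "vi"] = 1 - corrupted.loc[test_ids, "vi"]
    model2, row2 = run_outer_iteration(counts, corrupted, train_ids, test_ids,
                                       cfg, seed=13)
    model1.to_json(tmp_path / "m1.json")
    model2.to_json(tmp_path / "m2.json")
    assert (tmp_path / "m1.json").read_bytes() == (tmp_path / "m2.json").read_bytes()
    assert row1["panel"] == row2["panel"]
    assert row1["test_auroc"] != row2["test_auroc"]


# ---------------------------------------------------------------------------
# feature importance
# ---------------------------------------------------------------------------

def _model_with_coefs(coefs):
    genes = [f"g{i}" for i in range(len(coefs))]
    return PredictorModel(
        genes=genes,
        mean=pd.Series(0.0, index=genes),
        sd=pd.Series(1.0, index=genes),
        intercept=0.0,
        coef=pd.Series(coefs, index=genes),
        penalty=1.0,
    )


def test_feature_importance_single_nonzero_is_top_ranked():
    model = _model_with_coefs([0.0, 0.0, 2.0, 0.0])
    table, _ = feature_importance(model)
    assert table.index[0] == "g2"
    assert table["rank"].iloc[0] == 1.0


def test_feature_importance_all_tied_gives_ks_p_one():
    model = _model_with_coefs([0.5] * 8)
    clusters = SignatureClusters(
        assignments=pd.Series([1, 1, 1, 1, 2, 2, 2, 2],
                              index=model.genes),
        directions={1: "up", 2: "down"})
    _, ks = feature_importance(model, clusters)
    assert (ks["pvalue"] == 1.0).all()


def test_feature_importance_top_quartile_cluster_detected():
    from scipy.stats import ks_2samp
    coefs = np.concatenate([np.linspace(5, 4, 10),   # cluster 1: top ranks
                            np.linspace(1, 0.1, 30)])
    model = _model_with_coefs(coefs)
    clusters = SignatureClusters(
        assignments=pd.Series([1] * 10 + [2] * 30, index=model.genes),
        directions={1: "up", 2: "up"})
    table, ks = feature_importance(model, clusters)
    assert ks.at[1, "pvalue"] < 0.05
    # matches a direct two-sample KS computation on the ranks
    ranks = table["rank"]
    members = clusters.assignments
    oracle = ks_2samp(ranks[members == 1], ranks[members == 2])
    assert ks.at[1, "ks_stat"] == pytest.approx(oracle.statistic)
    assert ks.at[1, "pvalue"] == pytest.approx(oracle.pvalue)
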