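"""Cluster-proportional gene-panel selection and nested-CV ridge prediction.

The predictor is a binomial-logit GLM with an L2 (ridge) penalty on the gene
coefficients (intercept unpenalized), trained on standardized log-CPM of a
fixed-size gene panel.  The panel is drawn from the significant genes so that
each signature cluster contributes in proportion to its share of the
significant genes (largest-remainder apportionment), taking genes in
ascending p-value order within a cluster.

Honest performance estimation uses nested cross-validation: for each outer
stratified train/test split, differential expression, clustering, feature
selection, and the inner-fold ridge-penalty search are all re-run on the
outer-training samples only; the outer test samples contribute nothing but
the held-out AUROC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, mannwhitneyu, rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .config import PipelineConfig, stage_seed
from .diffexpr import estimate_dispersions, fit_nbglm_lrt, grade_design
from .preprocess import ExprMatrix, filter_genes, logcpm, tmm_factors
from .signature import SignatureClusters, cluster_signature

logger = logging.getLogger("visig")

__all__ = [
    "PredictorModel",
    "select_features",
    "train_ridge_logit",
    "nested_cv",
    "predict_scores",
    "auroc",
    "feature_importance",
]

_DEFAULT_LAMBDA_GRID = np.logspace(-3, 3, 30)


@dataclass
class PredictorModel:
    """A fitted ridge-logit gene-panel predictor.

    ``coef`` are on the standardized scale defined by ``mean``/``sd`` (the
    training statistics); ``predict_scores`` reapplies them verbatim to new
    cohorts after harmonization.
    """

    genes: list
    mean: pd.Series
    sd: pd.Series
    intercept: float
    coef: pd.Series
    penalty: float
    train_auroc: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.sd.to_numpy(float) <= 0).any():
            raise ValueError("standardization SDs must be positive")
        if not np.isfinite(self.coef.to_numpy(float)).all():
            raise ValueError("coefficients must be finite")

    def to_json(self, path) -> None:
        payload = {
            "genes": list(self.genes),
            "mean": self.mean.loc[self.genes].tolist(),
            "sd": self.sd.loc[self.genes].tolist(),
            "intercept": self.intercept,
            "coef": self.coef.loc[self.genes].tolist(),
            "penalty": self.penalty,
            "train_auroc": self.train_auroc,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "PredictorModel":
        payload = json.loads(Path(path).read_text())
        genes = payload["genes"]
        return cls(
            genes=genes,
            mean=pd.Series(payload["mean"], index=genes),
            sd=pd.Series(payload["sd"], index=genes),
            intercept=float(payload["intercept"]),
            coef=pd.Series(payload["coef"], index=genes),
            penalty=float(payload["penalty"]),
            train_auroc=payload.get("train_auroc"),
        )


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integerize ``fractions * total`` so the parts sum exactly to total."""
    raw = fractions * total
    floors = np.floor(raw).astype(int)
    shortfall = total - floors.sum()
    remainders = raw - floors
    order = np.lexsort((np.arange(len(raw)), -remainders))
    quotas = floors.copy()
    quotas[order[:shortfall]] += 1
    return quotas


def select_features(de: pd.DataFrame, clusters: SignatureClusters,
                    panel_size: int = 48,
                    fdr_threshold: float = 0.01) -> list:
    """Cluster-proportional panel of the most significant genes.

    Per-cluster quotas are ``panel_size`` times each cluster's share of the
    significant genes, integerized by largest remainder; quotas that exceed a
    cluster's significant-gene count are capped and the shortfall is
    redistributed (again by largest remainder) over the clusters with spare
    capacity.  Within a cluster genes are taken by ascending p-value, ties by
    descending |logFC| then gene ID.
    """
    sig = de[de["FDR"] < fdr_threshold]
    sig = sig[sig.index.isin(clusters.assignments.index)]
    n_sig = len(sig)
    if n_sig < panel_size:
        raise ValueError(f"only {n_sig} significant genes; panel needs "
                         f"{panel_size}")
    labels = clusters.assignments.reindex(sig.index)
    cluster_ids = np.array(sorted(labels.unique()))
    counts = np.array([(labels == c).sum() for c in cluster_ids])
    shares = counts / n_sig
    quotas = largest_remainder(shares, panel_size)

    # cap at availability and redistribute any excess
    for _ in range(len(cluster_ids)):
        over = quotas > counts
        if not over.any():
            break
        excess = int((quotas[over] - counts[over]).sum())
        quotas[over] = counts[over]
        spare = counts - quotas
        room = spare > 0
        if excess and room.any():
            shares_room = spare[room] / spare[room].sum()
            add = largest_remainder(shares_room, excess)
            add = np.minimum(add, spare[room])
            quotas[np.flatnonzero(room)] += add
    if quotas.sum() != panel_size:
        raise ValueError("quota redistribution failed to reach the panel size")

    panel = []
    for c, quota in zip(cluster_ids, quotas):
        members = sig[labels == c]
        order = sorted(members.index,
                       key=lambda g: (members.at[g, "PValue"],
                                      -abs(members.at[g, "logFC"]), g))
        panel.extend(order[:quota])
    return panel


# ---------------------------------------------------------------------------
# ridge-logit IRLS
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.clip(x, -60, 60)))


def _ridge_logit_irls(X: np.ndarray, y: np.ndarray, lam: float,
                      max_iter: int = 100, tol: float = 1e-10):
    """Maximize the L2-penalized logit log-likelihood by Newton/IRLS.

    The intercept is unpenalized.  Returns ``(intercept, coef)``.
    """
    n, p = X.shape
    Xa = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    pen = np.concatenate([[0.0], np.full(p, lam)])
    for _ in range(max_iter):
        eta = Xa @ beta
        prob = _sigmoid(eta)
        w = np.maximum(prob * (1 - prob), 1e-10)
        grad = Xa.T @ (y - prob) - pen * beta
        hess = (Xa * w[:, None]).T @ Xa + np.diag(pen + 1e-12)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return float(beta[0]), beta[1:]


def train_ridge_logit(expr_panel: pd.DataFrame, labels: pd.Series,
                      lambda_grid: Optional[np.ndarray] = None,
                      inner_folds: int = 5, seed: int = 0) -> PredictorModel:
    """Fit the ridge-logit panel model with inner-CV penalty selection.

    ``expr_panel`` is gene × sample logCPM restricted to the panel.  Features
    are standardized by training mean/SD; the ridge penalty is chosen to
    maximize the mean AUROC over stratified inner folds, then the final model
    is refit on all samples at the chosen penalty.
    """
    if lambda_grid is None:
        lambda_grid = _DEFAULT_LAMBDA_GRID
    y = labels.reindex(expr_panel.columns).to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X_raw = expr_panel.to_numpy(float).T  # samples × genes
    mean = X_raw.mean(axis=0)
    sd = X_raw.std(axis=0, ddof=1)
    sd = np.where(sd <= 0, 1.0, sd)
    X = (X_raw - mean) / sd

    if len(lambda_grid) > 1:
        splitter = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                                   random_state=seed % (2**31))
        fold_auroc = np.zeros((len(lambda_grid), inner_folds))
        for f, (tr, te) in enumerate(splitter.split(X, y)):
            for i, lam in enumerate(lambda_grid):
                b0, b = _ridge_logit_irls(X[tr], y[tr], lam)
                scores = _sigmoid(b0 + X[te] @ b)
                fold_auroc[i, f] = _auroc_point(scores, y[te])
        mean_auroc = fold_auroc.mean(axis=1)
        best = int(np.argmax(mean_auroc))
        lam = float(lambda_grid[best])
    else:
        lam = float(lambda_grid[0])

    b0, b = _ridge_logit_irls(X, y, lam)
    train_scores = _sigmoid(b0 + X @ b)
    model = PredictorModel(
        genes=list(expr_panel.index),
        mean=pd.Series(mean, index=expr_panel.index),
        sd=pd.Series(sd, index=expr_panel.index),
        intercept=b0,
        coef=pd.Series(b, index=expr_panel.index),
        penalty=lam,
        train_auroc=_auroc_point(train_scores, y),
    )
    return model


def predict_scores(model: PredictorModel, expr: ExprMatrix | pd.DataFrame,
                   scale: str = "probability") -> pd.Series:
    """Predicted VI score per sample from a fitted panel model.

    ``scale='probability'`` returns the logistic probability in (0, 1);
    ``scale='link'`` returns the linear predictor (log-odds), the scale used
    per standardized unit in the survival and heterogeneity analyses, where a
    near-separable fit would otherwise saturate the probabilities.
    """
    if scale not in ("probability", "link"):
        raise ValueError("scale must be 'probability' or 'link'")
    values = expr.values if isinstance(expr, ExprMatrix) else expr
    missing = [g for g in model.genes if g not in values.index]
    if missing:
        raise ValueError(f"{len(missing)} panel gene(s) missing from "
                         f"expression: {missing[:5]}")
    X = values.loc[model.genes].to_numpy(float).T
    Xs = (X - model.mean.loc[model.genes].to_numpy(float)) \
        / model.sd.loc[model.genes].to_numpy(float)
    eta = model.intercept + Xs @ model.coef.loc[model.genes].to_numpy(float)
    scores = eta if scale == "link" else _sigmoid(eta)
    return pd.Series(scores, index=values.columns, name="vi_score")


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def _auroc_point(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC as the normalized Mann–Whitney U (ties get half credit)."""
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auroc(scores: pd.Series, labels: pd.Series, n_boot: int = 2000,
          seed: int = 0) -> Dict[str, float]:
    """AUROC with a percentile-bootstrap 95% CI and a rank-sum null test.

    Bootstrap resamples the (score, label) pairs jointly; the reported
    p-value is the two-sided Wilcoxon rank-sum test of the scores between
    classes, whose null corresponds to AUROC = 0.5.
    """
    s = scores.to_numpy(float)
    y = labels.reindex(scores.index).to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    estimate = _auroc_point(s, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(s)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = _auroc_point(s[idx], y[idx])
    boots = boots[~np.isnan(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    p = mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").pvalue
    return {"auroc": estimate, "ci_low": float(lo), "ci_high": float(hi),
            "wilcoxon_p": float(p), "n": n}


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

def _cohort_logcpm(counts: pd.DataFrame, config: PipelineConfig,
                   prefiltered: bool = False) -> ExprMatrix:
    if not prefiltered:
        counts = filter_genes(counts, config.cpm_threshold, config.cpm_frac)
    factors = tmm_factors(counts)
    return logcpm(counts, factors)


def derive_panel(counts: pd.DataFrame, samples: pd.DataFrame,
                 config: PipelineConfig):
    """DE → clustering → cluster-proportional selection on one cohort.

    Returns ``(panel, de_table, clusters, expr)`` — the full signature
    derivation used both on the complete discovery cohort and inside each
    outer CV training split.
    """
    counts = filter_genes(counts, config.cpm_threshold, config.cpm_frac)
    factors = tmm_factors(counts)
    expr = logcpm(counts, factors)
    offset = np.log(counts.to_numpy(float).sum(axis=0)
                    * factors.to_numpy(float))
    X, names, contrast = grade_design(samples.loc[counts.columns])
    dispersions = estimate_dispersions(counts, X, offset=offset,
                                       design_names=names)
    de = fit_nbglm_lrt(counts, X, contrast, dispersions, offset=offset,
                       design_names=names)
    sig = de[de["FDR"] < config.fdr_threshold]
    if len(sig) < config.panel_size:
        raise ValueError(f"only {len(sig)} significant genes at "
                         f"FDR<{config.fdr_threshold}")
    clusters = cluster_signature(expr.values.loc[sig.index],
                                 k=config.n_clusters, logfc=sig["logFC"])
    panel = select_features(de, clusters, config.panel_size,
                            config.fdr_threshold)
    return panel, de, clusters, expr


def run_outer_iteration(counts: pd.DataFrame, samples: pd.DataFrame,
                        train_ids, test_ids, config: PipelineConfig,
                        seed: int):
    """One outer-CV iteration on an explicit train/test split.

    Everything that can learn — DE, clustering, feature selection, inner-fold
    penalty search, the final fit — sees only the training columns; the test
    columns contribute the held-out AUROC and nothing else.  Returns
    ``(model, summary_row)``.
    """
    y = samples.loc[counts.columns, "vi"].astype(int)
    train_counts = counts.loc[:, train_ids]
    panel, de, clusters, expr_train = derive_panel(
        train_counts, samples.loc[train_ids], config)
    model = train_ridge_logit(expr_train.values.loc[panel],
                              y.loc[train_ids],
                              inner_folds=config.inner_folds,
                              seed=seed)

    test_counts = counts.loc[expr_train.genes, test_ids]
    expr_test = _cohort_logcpm(test_counts, config, prefiltered=True)
    scores = predict_scores(model, expr_test)
    test_auroc = _auroc_point(scores.to_numpy(),
                              y.loc[test_ids].to_numpy(float))
    row = {
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "n_significant": int((de["FDR"] < config.fdr_threshold).sum()),
        "penalty": model.penalty,
        "train_auroc": model.train_auroc,
        "test_auroc": test_auroc,
        "panel": ",".join(panel),
    }
    return model, row


def nested_cv(counts: pd.DataFrame, samples: pd.DataFrame,
              config: Optional[PipelineConfig] = None,
              seed: Optional[int] = None,
              outer_iters: Optional[int] = None) -> pd.DataFrame:
    """Nested cross-validation of the full derivation + prediction pipeline.

    For each of ``outer_iters`` stratified 70/30 splits of the cohort, the
    signature (DE at the configured FDR, Ward clustering, cluster-
    proportional selection) is derived on the outer-training samples only; a
    ridge-logit model is trained with inner-fold penalty selection; and the
    held-out AUROC is recorded.  ``samples`` must carry ``grade`` and the
    binary ``vi`` label.  Returns one row per outer iteration.
    """
    config = config or PipelineConfig()
    if seed is None:
        seed = stage_seed(config.global_seed, "nested_cv")
    outer_iters = outer_iters or config.outer_iters
    y = samples.loc[counts.columns, "vi"].astype(int)

    rows = []
    for it in range(outer_iters):
        it_seed = (seed + 1000003 * it) % (2**31)
        attempts = 0
        while True:
            try:
                train_ids, test_ids = train_test_split(
                    counts.columns.to_numpy(), train_size=config.outer_train_frac,
                    stratify=y.to_numpy(),
                    random_state=(it_seed + attempts) % (2**31))
                if y.loc[train_ids].nunique() < 2 or y.loc[test_ids].nunique() < 2:
                    raise ValueError("split lacks a class")
                break
            except ValueError:
                attempts += 1
                if attempts > 50:
                    raise ValueError("could not build a stratified split with "
                                     "both classes") from None

        model, row = run_outer_iteration(counts, samples, train_ids, test_ids,
                                         config, it_seed)
        row["iteration"] = it
        rows.append(row)
        test_auroc = row["test_auroc"]
        logger.info("nested_cv iter %d: test AUROC %.3f (lambda %.3g)",
                    it, test_auroc, model.penalty)
    return pd.DataFrame(rows).set_index("iteration")


# ---------------------------------------------------------------------------
# feature importance
# ---------------------------------------------------------------------------

def feature_importance(model: PredictorModel,
                       clusters: Optional[SignatureClusters] = None):
    """Panel genes ranked by |standardized coefficient|.

    Returns ``(table, ks_table)``.  When ``clusters`` is given, each
    cluster's concentration toward the top ranks is tested by a two-sided
    two-sample KS test of the cluster members' ranks against the remaining
    panel genes' ranks (identical tied samples give D = 0, p = 1).
    """
    importance = model.coef.abs()
    ranks = pd.Series(rankdata(-importance.to_numpy()), index=importance.index)
    table = pd.DataFrame({
        "coef": model.coef,
        "importance": importance,
        "rank": ranks,
    }).sort_values("rank")
    if clusters is not None:
        table["cluster"] = clusters.assignments.reindex(table.index)

    ks_rows = []
    if clusters is not None:
        members = clusters.assignments.reindex(model.genes)
        for c in sorted(members.dropna().unique()):
            in_c = ranks[members == c].to_numpy()
            out_c = ranks[members != c].to_numpy()
            if len(in_c) == 0 or len(out_c) == 0:
                continue
            if np.ptp(np.concatenate([in_c, out_c])) == 0:
                stat, p = 0.0, 1.0
            else:
                res = ks_2samp(in_c, out_c, alternative="two-sided")
                stat, p = float(res.statistic), float(res.pvalue)
            ks_rows.append({"cluster": int(c), "n": len(in_c),
                            "ks_stat": stat, "pvalue": p})
    ks_table = pd.DataFrame(ks_rows).set_index("cluster") if ks_rows else \
        pd.DataFrame(columns=["n", "ks_stat", "pvalue"])
    return table, ks_table
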