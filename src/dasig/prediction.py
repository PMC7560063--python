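"""Supervised evaluation of gene signatures.

Severity (mild vs severe) is classified with a random forest under repeated
stratified 4-fold cross-validation, scored by AUROC averaged over repeats,
and contrasted with a random-gene baseline. Feature importance follows the
out-of-bag permutation recipe: per tree, the out-of-bag mean-squared error of
a regression forest on 0/1-coded labels is computed before and after
permuting one feature, and the importance is the mean error increase over
trees, averaged over repeated independent forests. Continuous FEV1/FVC
traits are regressed with SVR (RBF kernel) or LASSO under 4-fold CV with
out-of-fold predictions concatenated before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LassoCV
from sklearn.metrics import roc_auc_score, explained_variance_score
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.svm import SVR

from .matrix import ExpressionMatrix
from .signature import SignatureGeneList

N_TREES = 500
N_FOLDS = 4
N_REPEATS = 10
N_IMPORTANCE_TRIALS = 50
N_BASELINE_SAMPLINGS = 1000


@dataclass
class CVPredictionResult:
    """Out-of-fold predictions and the summary metric of one CV experiment."""

    sample_ids: list
    truth: np.ndarray
    predictions: np.ndarray          # out-of-fold predictions, last repeat
    fold_assignment: np.ndarray      # fold index per sample, last repeat
    metric_name: str
    metric_value: float
    per_repeat_metric: list = field(default_factory=list)
    n_repeats: int = 1
    seed: int = 0
    metrics: dict = field(default_factory=dict)


def auroc(scores, labels) -> float:
    """AUROC = P(random positive outranks random negative), ties count half."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("labels must contain exactly two classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _encode_binary(labels, positive: str | None = None):
    labels = np.asarray([str(l) for l in labels])
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError(f"exactly two classes required, got {levels}")
    if positive is None:
        positive = "severe" if "severe" in levels else levels[1]
    return (labels == positive).astype(int), positive


def rf_severity_cv(X: ExpressionMatrix, labels, n_folds: int = N_FOLDS,
                   n_repeats: int = N_REPEATS, n_trees: int = N_TREES,
                   seed: int = 0) -> CVPredictionResult:
    """Repeated stratified k-fold random-forest classification, AUROC-scored.

    ``X`` is the expression matrix restricted to the signature genes; samples
    are columns and features genes. The reported metric is the mean over
    repeats of the AUROC computed on each repeat's out-of-fold class-1
    probabilities. Deterministic under ``seed``.
    """
    y, positive = _encode_binary(labels)
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise ValueError(f"each class needs >= {n_folds} samples for {n_folds}-fold CV")
    data = X.values.T  # samples x genes
    rng = np.random.default_rng(seed)
    per_repeat = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        oof = np.empty(len(y))
        folds = np.empty(len(y), dtype=int)
        for f, (tr, te) in enumerate(skf.split(data, y)):
            clf = RandomForestClassifier(
                n_estimators=n_trees, max_features="sqrt",
                random_state=int(rng.integers(2**31)), n_jobs=1,
            ).fit(data[tr], y[tr])
            oof[te] = clf.predict_proba(data[te])[:, list(clf.classes_).index(1)]
            folds[te] = f
        per_repeat.append(auroc(oof, y))
    return CVPredictionResult(
        sample_ids=list(X.sample_ids), truth=y, predictions=oof,
        fold_assignment=folds, metric_name="auroc",
        metric_value=float(np.mean(per_repeat)), per_repeat_metric=per_repeat,
        n_repeats=n_repeats, seed=seed,
    )


def random_gene_baseline(X_full: ExpressionMatrix, labels, n_genes: int = 50,
                         n_samplings: int = N_BASELINE_SAMPLINGS,
                         n_folds: int = N_FOLDS, n_repeats: int = 1,
                         n_trees: int = N_TREES, seed: int = 0):
    """AUROC distribution of classifiers built on random gene subsets.

    Each sampling draws ``n_genes`` genes uniformly without replacement and
    runs the same CV as the signature classifier (repeats reducible for
    speed). Returns (mean AUROC, per-sampling array).
    """
    if n_genes > X_full.n_genes:
        raise ValueError("n_genes exceeds the gene count")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_samplings)
    for s in range(n_samplings):
        picks = rng.choice(X_full.n_genes, size=n_genes, replace=False)
        sub = ExpressionMatrix([X_full.gene_ids[i] for i in picks],
                               list(X_full.sample_ids), X_full.values[picks, :])
        res = rf_severity_cv(sub, labels, n_folds=n_folds, n_repeats=n_repeats,
                             n_trees=n_trees, seed=int(rng.integers(2**31)))
        scores[s] = res.metric_value
    return float(scores.mean()), scores


def oob_permutation_importance(X: ExpressionMatrix, labels,
                               n_trees: int = N_TREES,
                               n_trials: int = N_IMPORTANCE_TRIALS,
                               seed: int = 0) -> pd.DataFrame:
    """Out-of-bag permutation importance of every gene, averaged over trials.

    Labels are 0/1-coded and fit with a regression forest. For each tree the
    OOB mean-squared error is computed before and after permuting one
    feature among the tree's OOB samples; a feature's importance in one
    trial is the mean error increase over trees with usable (>= 2 sample)
    OOB sets, and the table reports the mean and SD over ``n_trials``
    independently seeded forests, plus the per-trial values.
    """
    if X.n_genes < 2:
        raise ValueError("need >= 2 features")
    y, _ = _encode_binary(labels)
    data = X.values.T  # samples x genes
    n_samples, n_features = data.shape
    rng = np.random.default_rng(seed)
    trial_values = np.zeros((n_trials, n_features))
    n_degenerate = 0
    for trial in range(n_trials):
        forest = RandomForestRegressor(
            n_estimators=n_trees, max_features="sqrt", bootstrap=True,
            random_state=int(rng.integers(2**31)), n_jobs=1,
        ).fit(data, y)
        per_tree = np.zeros((len(forest.estimators_), n_features))
        used = np.zeros(len(forest.estimators_), dtype=bool)
        for t, (tree, sampled) in enumerate(
                zip(forest.estimators_, forest.estimators_samples_)):
            oob_mask = np.ones(n_samples, dtype=bool)
            oob_mask[sampled] = False
            oob_idx = np.nonzero(oob_mask)[0]
            if oob_idx.size < 2:
                n_degenerate += 1
                continue
            used[t] = True
            X_oob = np.asarray(data[oob_idx], dtype=np.float32)
            y_oob = y[oob_idx]
            m = oob_idx.size
            base_mse = np.mean((tree.predict(X_oob) - y_oob) ** 2)
            # permuting a feature the tree never splits on cannot change its
            # predictions, so only the tree's split features need evaluating
            split_feats = np.unique(tree.tree_.feature)
            split_feats = split_feats[split_feats >= 0]
            if split_feats.size == 0:
                continue
            blocks = np.tile(X_oob, (split_feats.size, 1))
            for k, f in enumerate(split_feats):
                blocks[k * m:(k + 1) * m, f] = X_oob[rng.permutation(m), f]
            preds = tree.predict(blocks).reshape(split_feats.size, m)
            perm_mse = np.mean((preds - y_oob) ** 2, axis=1)
            per_tree[t, split_feats] = perm_mse - base_mse
        if used.any():
            trial_values[trial] = per_tree[used].mean(axis=0)
    table = pd.DataFrame(
        {
            "gene": X.gene_ids,
            "importance": trial_values.mean(axis=0),
            "importance_sd": trial_values.std(axis=0, ddof=1) if n_trials > 1
            else np.zeros(n_features),
        }
    )
    table.attrs["trial_values"] = trial_values
    table.attrs["n_degenerate_oob"] = n_degenerate
    return table


def select_top_features(table: pd.DataFrame, k: int = 50) -> SignatureGeneList:
    """Top-k genes by mean importance; ties broken lexicographically."""
    if k > len(table):
        raise ValueError("k exceeds the number of features")
    ranked = table.sort_values(["importance", "gene"],
                               ascending=[False, True], kind="stable")
    top = ranked.head(k)
    return SignatureGeneList(
        list(top["gene"]),
        importance={g: float(v) for g, v in zip(top["gene"], top["importance"])},
    )


def regress_trait(X: ExpressionMatrix, y, method: str = "svr",
                  n_folds: int = N_FOLDS, seed: int = 0) -> CVPredictionResult:
    """k-fold CV regression of a continuous trait from gene expression.

    Out-of-fold predictions from all folds are concatenated (in sample
    order) and scored once: Pearson r, MSE and explained variance. SVR uses
    an RBF kernel with C=1, epsilon=0.1; LASSO picks its penalty by internal
    cross-validation on the training folds only.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trait values must be finite")
    if np.allclose(y, y[0]):
        raise ValueError("constant trait: correlation undefined")
    if len(y) < n_folds:
        raise ValueError("need at least n_folds samples")
    if method not in ("svr", "lasso"):
        raise ValueError("method must be 'svr' or 'lasso'")
    data = X.values.T
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.empty(len(y))
    folds = np.empty(len(y), dtype=int)
    for f, (tr, te) in enumerate(kf.split(data)):
        if method == "svr":
            est = SVR(kernel="rbf", C=1.0, epsilon=0.1)
        else:
            est = LassoCV(cv=3, random_state=seed, max_iter=5000)
        est.fit(data[tr], y[tr])
        oof[te] = est.predict(data[te])
        folds[te] = f
    r = float(stats.pearsonr(oof, y)[0]) if np.ptp(oof) > 0 else 0.0
    mse = float(np.mean((oof - y) ** 2))
    ev = float(explained_variance_score(y, oof))
    return CVPredictionResult(
        sample_ids=list(X.sample_ids), truth=y, predictions=oof,
        fold_assignment=folds, metric_name="pearson_r", metric_value=r,
        per_repeat_metric=[r], n_repeats=1, seed=seed,
        metrics={"pearson_r": r, "mse": mse, "explained_variance": ev},
    )
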