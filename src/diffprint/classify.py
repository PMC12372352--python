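"""Medium classification from fingerprint tables.

A panel of seven classifiers spanning three families (linear models,
instance-based learners, tree ensembles) is evaluated with either a
stratified 70/30 holdout or stratified fivefold cross-validation.
Metrics are accuracy and macro-averaged precision/recall/F1 (macro so
every class weighs equally regardless of imbalance).  Features are
z-scored inside each training fold by default to avoid leakage; a
'global' mode standardizes once on the full table before splitting.

Per-class feature attributions for the gradient-boosting model are
Shapley values estimated by Monte-Carlo permutation sampling of the
model's predicted class probabilities (marginal contributions averaged
over random feature orderings against a background sample); the reported
importance is the mean absolute attribution per feature and class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .types import FEATURE_NAMES

TREE_ENSEMBLES = ("hist_gradient_boosting", "random_forest")


def classifier_panel(seed: int = 0) -> dict:
    """The seven-member classifier panel with library-default settings."""
    return {
        "svm_rbf": SVC(kernel="rbf", random_state=seed),
        "knn": KNeighborsClassifier(),
        "hist_gradient_boosting": HistGradientBoostingClassifier(random_state=seed),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "logistic_regression": LogisticRegression(max_iter=2000, random_state=seed),
        "random_forest": RandomForestClassifier(random_state=seed),
        "lda": LinearDiscriminantAnalysis(),
    }


@dataclass
class ClassificationReport:
    """Per-fold metrics, summaries and confusion matrices of a panel run."""

    protocol: str
    seed: int
    class_labels: list
    fold_metrics: pd.DataFrame        # classifier, fold, accuracy, precision, recall, f1
    summary: pd.DataFrame             # per classifier: mean/sd of each metric
    confusions: dict                  # classifier -> (C, C) count matrix over folds
    best_classifier: str
    standardize_mode: str
    n_rows: int


def _prepare(table: pd.DataFrame, label_col: str, exclude_flagged: bool):
    if exclude_flagged and "flagged" in table.columns:
        table = table[~table["flagged"]]
    X = table[FEATURE_NAMES].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    if np.isnan(X).any():
        raise ValueError("NaN features present; exclude flagged rows first")
    labels = sorted(pd.unique(y))
    if len(labels) < 2:
        raise ValueError("need at least 2 classes to classify")
    counts = pd.Series(y).value_counts()
    if (counts < 10).any():
        import warnings
        warnings.warn(f"classes with < 10 rows: {dict(counts[counts < 10])}")
    return X, y, labels


def _splits(protocol: str, X, y, seed: int):
    if protocol == "cv_5fold":
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        yield from cv.split(X, y)
    elif protocol == "holdout_70_30":
        idx = np.arange(len(y))
        train, test = train_test_split(idx, test_size=0.3, stratify=y,
                                       random_state=seed)
        yield train, test
    else:
        raise ValueError(f"unknown protocol {protocol!r}")


def train_panel(table: pd.DataFrame, protocol: str = "cv_5fold", seed: int = 0,
                label_col: str = "medium", standardize_mode: str = "fit_on_train",
                exclude_flagged: bool = True) -> ClassificationReport:
    """Train and evaluate the seven-classifier panel.

    Stratified splitting throughout; a class absent from a training fold
    raises.  Deterministic given (table, protocol, seed).
    """
    X, y, labels = _prepare(table, label_col, exclude_flagged)
    if standardize_mode == "global":
        X = StandardScaler().fit_transform(X)
    elif standardize_mode != "fit_on_train":
        raise ValueError("standardize_mode must be 'fit_on_train' or 'global'")

    records = []
    confusions = {name: np.zeros((len(labels), len(labels)), dtype=np.int64)
                  for name in classifier_panel(seed)}
    for fold, (train, test) in enumerate(_splits(protocol, X, y, seed)):
        if len(set(y[train])) < len(labels):
            raise ValueError(f"fold {fold}: a class is absent from training data")
        Xtr, Xte = X[train], X[test]
        if standardize_mode == "fit_on_train":
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        for name, clf in classifier_panel(seed).items():
            clf.fit(Xtr, y[train])
            pred = clf.predict(Xte)
            prec, rec, f1, _ = precision_recall_fscore_support(
                y[test], pred, average="macro", zero_division=0)
            records.append({
                "classifier": name, "fold": fold,
                "accuracy": accuracy_score(y[test], pred),
                "precision": prec, "recall": rec, "f1": f1,
            })
            confusions[name] += confusion_matrix(y[test], pred, labels=labels)

    fold_metrics = pd.DataFrame(records)
    summary = (fold_metrics.groupby("classifier")
               [["accuracy", "precision", "recall", "f1"]]
               .agg(["mean", "std"]))
    best = summary[("f1", "mean")].idxmax()
    return ClassificationReport(
        protocol=protocol, seed=seed, class_labels=labels,
        fold_metrics=fold_metrics, summary=summary, confusions=confusions,
        best_classifier=best, standardize_mode=standardize_mode,
        n_rows=len(y))


def confusion(report: ClassificationReport,
              classifier: str | None = None) -> pd.DataFrame:
    """Row-normalized confusion matrix (per-class recall on the diagonal).

    Aggregated over folds; rows sum to 1.  Defaults to the report's best
    classifier.
    """
    name = classifier or report.best_classifier
    counts = report.confusions[name].astype(float)
    row_sums = counts.sum(axis=1, keepdims=True)
    norm = np.divide(counts, row_sums, out=np.zeros_like(counts),
                     where=row_sums > 0)
    return pd.DataFrame(norm, index=report.class_labels,
                        columns=report.class_labels)


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

def embed(table: pd.DataFrame, method: str = "lda_1d", seed: int = 0,
          label_col: str = "medium", exclude_flagged: bool = True) -> np.ndarray:
    """Low-dimensional embedding of the standardized fingerprint table.

    ``lda_1d`` projects onto the leading Fisher discriminant (supervised,
    at most n_classes - 1 components); ``tsne_2d`` is a seeded 2-D t-SNE
    layout.  Returns one coordinate row per (non-flagged) table row.
    """
    X, y, labels = _prepare(table, label_col, exclude_flagged)
    X = StandardScaler().fit_transform(X)
    if method == "lda_1d":
        lda = LinearDiscriminantAnalysis(n_components=1, solver="eigen",
                                         shrinkage="auto")
        return lda.fit_transform(X, y)
    if method == "tsne_2d":
        perplexity = min(30.0, max(2.0, (len(X) - 1) / 3.0))
        tsne = TSNE(n_components=2, random_state=seed, init="pca",
                    perplexity=perplexity)
        return tsne.fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}")


# ---------------------------------------------------------------------------
# Shapley-value feature importance for the tree model
# ---------------------------------------------------------------------------

@dataclass
class ShapSummary:
    """Per-class mean absolute Shapley attributions and their ranking."""

    per_class: pd.DataFrame     # features x classes, mean |attribution|
    total: pd.Series            # per-feature sum across classes
    ranking: list               # features sorted by descending total
    top: pd.DataFrame           # per_class restricted to the top_k features
    classes: list


def _sampled_shapley(model, X_explain: np.ndarray, X_background: np.ndarray,
                     n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo Shapley values of predict_proba for each explained row.

    For each random feature ordering, features are switched one at a time
    from a background draw to the explained row; the change in predicted
    class probability is the feature's marginal contribution.  Averaging
    over orderings estimates the Shapley value; contributions per row sum
    to f(x) - f(background draw) by construction.
    Returns an (n_explain, n_features, n_classes) array.
    """
    n, p = X_explain.shape
    n_classes = len(model.classes_)
    phi = np.zeros((n, p, n_classes))
    for _ in range(n_permutations):
        perm = rng.permutation(p)
        z = X_background[rng.integers(0, len(X_background), size=n)]
        cur = z.copy()
        prev = model.predict_proba(cur)
        for j in perm:
            cur[:, j] = X_explain[:, j]
            nxt = model.predict_proba(cur)
            phi[:, j, :] += nxt - prev
            prev = nxt
    return phi / n_permutations


def shap_importance(table: pd.DataFrame, seed: int = 0, top_k: int = 5,
                    label_col: str = "medium", model: str = "hist_gradient_boosting",
                    n_permutations: int = 20, n_explain: int = 100,
                    n_background: int = 100,
                    exclude_flagged: bool = True) -> ShapSummary:
    """Per-class feature importance of the gradient-boosting classifier.

    The model is trained on the standardized table; mean absolute
    Shapley attributions of its predicted class probabilities are
    computed per feature and class, and features are ranked by their
    total across classes (top_k reported for stacked-bar display).
    Deterministic given (table, seed).
    """
    if model != "hist_gradient_boosting":
        raise ValueError(
            "Shapley attribution is provided for the tree model only "
            "('hist_gradient_boosting'); use permutation importance for others")
    X, y, labels = _prepare(table, label_col, exclude_flagged)
    X = StandardScaler().fit_transform(X)
    clf = HistGradientBoostingClassifier(random_state=seed).fit(X, y)
    rng = np.random.default_rng(seed)
    explain_idx = rng.choice(len(X), size=min(n_explain, len(X)), replace=False)
    background_idx = rng.choice(len(X), size=min(n_background, len(X)),
                                replace=False)
    phi = _sampled_shapley(clf, X[explain_idx], X[background_idx],
                           n_permutations, rng)
    mean_abs = np.abs(phi).mean(axis=0)  # (features, classes)
    per_class = pd.DataFrame(mean_abs, index=FEATURE_NAMES,
                             columns=list(clf.classes_))
    total = per_class.sum(axis=1)
    ranking = list(total.sort_values(ascending=False).index)
    return ShapSummary(per_class=per_class, total=total, ranking=ranking,
                       top=per_class.loc[ranking[:top_k]],
                       classes=list(clf.classes_))
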