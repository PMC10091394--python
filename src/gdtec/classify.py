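"""Subtype classifiers: random forest on GDTEC features, Gini-importance
selection, ROC/AUC, the external CNV-fraction labeling rule, and KNN label
transfer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .omics_io import GdtecError, GeneSampleMatrix

__all__ = [
    "ClassifierFit",
    "ROCResult",
    "train_rf",
    "gini_select",
    "roc_auc",
    "cnv_rule_label",
    "knn_transfer",
]


@dataclass
class ClassifierFit:
    """A trained random-forest classifier with importances and held-out scores."""

    model: RandomForestClassifier
    importances: pd.Series  # mean decrease in Gini impurity per feature
    test_scores: pd.Series  # P(positive class) per held-out sample
    test_labels: pd.Series  # true labels of the held-out samples
    predicted: pd.Series  # predicted label at the 0.5 threshold
    train_ids: list[str]
    test_ids: list[str]
    positive_class: str
    seed: int
    params: dict = field(default_factory=dict)


@dataclass
class ROCResult:
    """ROC points and the AUC (Mann-Whitney concordance, ties at half)."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def train_rf(
    features: pd.DataFrame,
    labels: pd.Series,
    positive_class: str = "Mix_Sub",
    train_fraction: float = 0.7,
    n_trees: int = 500,
    seed: int = 0,
) -> ClassifierFit:
    """Train a random forest on samples x features with a stratified split.

    Importances are scikit-learn's mean decrease in Gini impurity (normalized
    to sum to 1 across features); fully reproducible for a fixed seed.
    """
    labels = labels.reindex(features.index)
    if labels.isna().any():
        raise GdtecError("labels missing for some samples")
    if labels.nunique() < 2:
        raise GdtecError("training labels contain a single class")
    X_train, X_test, y_train, y_test = train_test_split(
        features,
        labels,
        train_size=train_fraction,
        stratify=labels,
        random_state=seed % (2**31 - 1),
    )
    if y_train.nunique() < 2:
        raise GdtecError("training split contains a single class")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed % (2**31 - 1),
    )
    rf.fit(X_train.to_numpy(), (y_train == positive_class).astype(int))
    scores = rf.predict_proba(X_test.to_numpy())[:, 1]
    predicted = np.where(scores >= 0.5, positive_class, "other")
    return ClassifierFit(
        model=rf,
        importances=pd.Series(rf.feature_importances_, index=features.columns),
        test_scores=pd.Series(scores, index=X_test.index),
        test_labels=y_test,
        predicted=pd.Series(predicted, index=X_test.index),
        train_ids=list(X_train.index),
        test_ids=list(X_test.index),
        positive_class=positive_class,
        seed=seed,
        params={"n_trees": n_trees, "train_fraction": train_fraction},
    )


def gini_select(
    fit: ClassifierFit, mode: str = "threshold", value: float | int = 0.0
) -> list[str]:
    """Select features by Gini importance.

    ``threshold`` keeps features with importance strictly greater than
    ``value``; ``top_n`` keeps the ``value`` largest (ties broken by feature
    ID order).
    """
    imp = fit.importances
    if mode == "threshold":
        return list(imp.index[imp > value])
    if mode == "top_n":
        n = int(value)
        if n >= len(imp):
            if n > len(imp):
                import logging

                logging.getLogger("gdtec").warning(
                    "top_n=%d exceeds %d features; keeping all", n, len(imp)
                )
            return list(imp.index)
        order = imp.sort_values(ascending=False, kind="stable")
        # stable sort on (-importance, feature ID) for deterministic ties
        ranked = sorted(imp.index, key=lambda g: (-imp[g], g))
        return ranked[:n]
    raise ValueError(f"unknown mode {mode!r}")


def roc_auc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> ROCResult:
    """ROC curve and AUC.

    AUC is the Mann-Whitney concordance probability: the fraction of
    (positive, negative) pairs where the positive scores higher, ties
    counted as half.
    """
    s = np.asarray(pd.Series(scores), dtype=float)
    y = np.asarray(pd.Series(labels)).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise GdtecError("roc_auc requires both classes present")
    # threshold sweep over unique scores, descending
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep the last point of each tied-score run
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc)


def cnv_rule_label(
    cnv_calls: GeneSampleMatrix,
    marker_genes: list[str],
    min_fraction: float = 0.8,
) -> pd.Series:
    """External-cohort labeling: Mix_Sub iff MORE than ``min_fraction`` of the
    marker genes present in the matrix have a nonzero CNV call (strict >)."""
    present = [g for g in marker_genes if g in cnv_calls.values.index]
    if not present:
        raise GdtecError("none of the marker genes are present in the CNV matrix")
    sub = cnv_calls.values.loc[present]
    frac = (sub.to_numpy() != 0).mean(axis=0)
    labels = np.where(frac > min_fraction, "Mix_Sub", "non-Mix_Sub")
    return pd.Series(labels, index=cnv_calls.sample_ids, name="cnv_rule_label")


def knn_transfer(
    train_features: pd.DataFrame,
    train_labels: pd.Series,
    test_features: pd.DataFrame,
    k: int = 5,
    distance: str = "euclidean",
) -> pd.Series:
    """k-nearest-neighbor label transfer with a deterministic tie-break.

    Majority vote among the k nearest training samples; a tied vote goes to
    the class with the smaller mean distance among the k neighbors.  k must
    be odd (binary votes cannot tie then, but multi-class ones still can).
    """
    if k % 2 == 0:
        raise GdtecError("k must be odd")
    if k > len(train_features):
        raise GdtecError("k exceeds the training-set size")
    if list(train_features.columns) != list(test_features.columns):
        raise GdtecError("train and test feature spaces differ")
    metric = {"euclidean": "euclidean", "jaccard": "jaccard"}[distance]
    D = cdist(test_features.to_numpy(), train_features.to_numpy(), metric=metric)
    D = np.nan_to_num(D, nan=0.0)  # jaccard of two all-zero rows
    y = train_labels.reindex(train_features.index).to_numpy()
    out = []
    for row in D:
        nn = np.argsort(row, kind="stable")[:k]
        votes = pd.Series(y[nn]).value_counts()
        top = votes[votes == votes.max()].index
        if len(top) == 1:
            out.append(top[0])
        else:
            means = {
                lab: row[nn][y[nn] == lab].mean() for lab in top
            }
            out.append(min(means, key=lambda lab: (means[lab], str(lab))))
    return pd.Series(out, index=test_features.index, name="knn_label")
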