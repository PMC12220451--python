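"""Ingredient–disease link prediction.

Every ingredient–disease edge of the network is a positive example;
negatives are sampled uniformly without replacement from the non-edge
ingredient × disease pairs at a configurable ratio (link prediction on
these networks is severely imbalanced, so the ratio is the main knob
affecting precision–recall behaviour).  An ingredient feature vector
F_C and a disease feature vector F_D are fused into a pair feature by
the Hadamard (elementwise) product, and a random forest scores the
pair with its positive-class probability.  Candidate diseases for an
ingredient are ranked by that score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split

from .hetnet import HeterogeneousNetwork, ValidationError

__all__ = [
    "MetricsReport",
    "build_pair_dataset",
    "hadamard_fuse",
    "split_dataset",
    "pair_features",
    "train_classifier",
    "evaluate",
    "rank_diseases",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """Metrics requested on a record set with only one class."""


@dataclass(frozen=True)
class MetricsReport:
    """The six evaluation metrics: AUC, AUPR (average precision),
    accuracy, precision, recall and F1 of the positive class."""

    auc: float
    aupr: float
    accuracy: float
    precision: float
    recall: float
    f1: float

    def to_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def build_pair_dataset(
    net: HeterogeneousNetwork,
    negative_ratio: float | str = 10,
    seed: int = 0,
    exclude: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Labelled ingredient–disease pairs from a network.

    All ingredient–disease edges become positives (label 1); negatives
    (label 0) are drawn uniformly without replacement from the
    non-edge ingredient × disease pairs, ``negative_ratio`` per
    positive, or exhaustively with ``negative_ratio="all"``.  Pairs in
    ``exclude`` are never sampled as negatives (used to keep held-out
    positives out of the negative pool).  Reproducible under ``seed``.
    """
    positives = net.edges_of_relation("ingredient-disease")
    if not positives:
        raise ValidationError("network has no ingredient-disease edges")
    exclude = exclude or set()
    pos_set = set(positives)
    ingredients = net.nodes_of_type("ingredient")
    diseases = net.nodes_of_type("disease")
    candidates = [
        (i, d)
        for i in ingredients
        for d in diseases
        if (i, d) not in pos_set and (i, d) not in exclude
    ]
    if negative_ratio == "all":
        n_neg = len(candidates)
    else:
        if not negative_ratio > 0:
            raise ValidationError(f"negative_ratio must be positive, got {negative_ratio}")
        n_neg = int(round(negative_ratio * len(positives)))
    if n_neg > len(candidates):
        warnings.warn(
            f"requested {n_neg} negatives but only {len(candidates)} non-edge "
            "pairs exist; capping"
        )
        n_neg = len(candidates)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_neg, replace=False) if n_neg else []
    rows = [
        {"ingredient": i, "disease": d, "label": 1} for i, d in positives
    ] + [
        {"ingredient": candidates[k][0], "disease": candidates[k][1], "label": 0}
        for k in sorted(chosen)
    ]
    return pd.DataFrame(rows, columns=["ingredient", "disease", "label"])


def hadamard_fuse(fc: np.ndarray, fd: np.ndarray) -> np.ndarray:
    """Elementwise product of an ingredient and a disease feature vector."""
    fc = np.asarray(fc, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if fc.shape != fd.shape:
        raise ValidationError(
            f"feature length mismatch: {fc.shape} vs {fd.shape}"
        )
    return fc * fd


def pair_features(
    pairs: pd.DataFrame, features: pd.DataFrame
) -> np.ndarray:
    """Hadamard pair-feature matrix for a pair table, one row per pair."""
    fc = features.loc[pairs["ingredient"]].to_numpy(dtype=float)
    fd = features.loc[pairs["disease"]].to_numpy(dtype=float)
    return fc * fd


def split_dataset(
    pairs: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test partition at ``train_fraction`` (default the
    8:2 split), stratified by label so the minority class stays present
    in the test set.  Falls back to an unstratified split, with a
    warning, when a class has fewer than 2 members."""
    if not 0 < train_fraction < 1:
        raise ValidationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if len(pairs) < 2:
        raise ValidationError("need at least 2 pairs to split")
    stratify = pairs["label"]
    if stratify.value_counts().min() < 2:
        warnings.warn("a label class has <2 members; splitting without stratification")
        stratify = None
    train, test = train_test_split(
        pairs,
        train_size=train_fraction,
        random_state=seed,
        stratify=stratify,
        shuffle=True,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def train_classifier(
    x: np.ndarray, y: np.ndarray, seed: int = 0, n_trees: int = 100
) -> RandomForestClassifier:
    """Fit the random-forest link predictor.

    100 trees, unlimited depth, sqrt(d) features per split; scoring is
    the positive-class probability.  ``n_jobs=1`` keeps training
    deterministic under ``seed``.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("training set contains a single class")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(np.asarray(x, dtype=float), y)
    return clf


def score_pairs(clf: RandomForestClassifier, x: np.ndarray) -> np.ndarray:
    """Positive-class probabilities in [0, 1]."""
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return clf.predict_proba(np.asarray(x, dtype=float))[:, pos_col]


def evaluate(records: pd.DataFrame, threshold: float = 0.5) -> MetricsReport:
    """Compute the six metrics from a table with ``score`` and
    ``true_label`` columns.

    AUC is the rank-based ROC area (ties count 1/2); AUPR is average
    precision (step-wise interpolation of the PR curve).  Accuracy,
    precision, recall and F1 are computed for the positive class after
    thresholding scores at ``threshold`` (score >= threshold → 1).
    """
    y = records["true_label"].to_numpy()
    s = records["score"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("records contain a single class; AUC undefined")
    pred = (s >= threshold).astype(int)
    return MetricsReport(
        auc=float(roc_auc_score(y, s)),
        aupr=float(average_precision_score(y, s)),
        accuracy=float(accuracy_score(y, pred)),
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        f1=float(f1_score(y, pred, zero_division=0)),
    )


def rank_diseases(
    ingredient: str,
    clf: RandomForestClassifier,
    features: pd.DataFrame,
    diseases: list[str],
    known_positives: set[tuple[str, str]] | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score every disease against one ingredient and sort descending.

    Ties are broken by disease id (lexicographic) for a stable,
    reproducible ordering.  When ``known_positives`` is given, a
    ``true_label`` column marks pairs present in that reference set.
    """
    if ingredient not in features.index:
        raise KeyError(f"no feature row for ingredient {ingredient!r}")
    missing = [d for d in diseases if d not in features.index]
    if missing:
        raise KeyError(f"no feature rows for diseases {missing[:10]}")
    diseases = sorted(diseases)
    fc = features.loc[ingredient].to_numpy(dtype=float)
    fd = features.loc[diseases].to_numpy(dtype=float)
    scores = score_pairs(clf, fc[None, :] * fd)
    out = pd.DataFrame(
        {
            "ingredient": ingredient,
            "disease": diseases,
            "score": scores,
            "predicted_label": (scores >= threshold).astype(int),
        }
    )
    if known_positives is not None:
        out["true_label"] = [
            int((ingredient, d) in known_positives) for d in diseases
        ]
    out = out.sort_values(
        ["score", "disease"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
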