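"""Screening classifiers: predict the MI-performance group from resting
alpha features.

Binary screening separates the high group (H) from the low group (L) with a
linear SVM (C=1) on the eyes-open alpha channel-pair features — each single
feature alone and the three combined.  The three-class model adds the medium
group and reports the full prediction distribution (confusion matrix), which
exposes where the medium group's resting features fall.

Feature standardization is fitted inside each training fold; folds are
stratified.  Class imbalance is left unweighted by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

GROUP_ORDER = ("H", "M", "L")


@dataclass
class ScreeningResult:
    feature_set: str
    cv_accuracy: float  # %, pooled over folds (== confusion diagonal share)
    fold_accuracies: np.ndarray
    confusion: pd.DataFrame  # rows true group, columns predicted group
    seed: int
    predictions: pd.Series | None = None  # subject -> predicted group
    fold_of: pd.Series | None = None  # subject -> test-fold index

    def prediction_distribution(self) -> pd.DataFrame:
        """P(predicted | true): confusion rows normalized to 1."""
        return self.confusion.div(self.confusion.sum(axis=1), axis=0)


def _cv_screen(
    x: np.ndarray,
    y: np.ndarray,
    feature_set: str,
    folds: int,
    seed: int,
    class_weight=None,
    index=None,
    reps: int = 1,
) -> ScreeningResult:
    classes = [g for g in GROUP_ORDER if g in set(y)]
    min_class = min((y == c).sum() for c in classes)
    if min_class < folds:
        warnings.warn(
            f"smallest group has {min_class} subjects; reducing folds "
            f"from {folds} to {min_class}"
        )
        folds = min_class
    if folds < 2:
        raise ValueError("need at least 2 subjects per group to cross-validate")

    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    fold_acc = []
    all_pred = np.empty(len(y), dtype=object)
    fold_of = np.empty(len(y), dtype=int)
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for f, (train_idx, test_idx) in enumerate(skf.split(x, y)):
            clf = make_pipeline(
                StandardScaler(), SVC(kernel="linear", C=1.0, class_weight=class_weight)
            )
            clf.fit(x[train_idx], y[train_idx])
            pred = clf.predict(x[test_idx])
            if rep == 0:
                all_pred[test_idx] = pred
                fold_of[test_idx] = f
            fold_acc.append(np.mean(pred == y[test_idx]))
            for t, p in zip(y[test_idx], pred):
                confusion.loc[t, p] += 1
    # pooled over folds (and repetitions): exactly the confusion's diagonal share
    accuracy = 100.0 * np.trace(confusion.to_numpy()) / confusion.to_numpy().sum()
    return ScreeningResult(
        feature_set=feature_set,
        cv_accuracy=float(accuracy),
        fold_accuracies=np.asarray(fold_acc),
        confusion=confusion,
        seed=seed,
        predictions=pd.Series(all_pred, index=index),
        fold_of=pd.Series(fold_of, index=index),
    )


def screen_binary(
    pair_features: pd.DataFrame,
    groups: pd.Series,
    folds: int = 10,
    seed: int = 0,
    class_weight=None,
    reps: int = 1,
) -> dict[str, ScreeningResult]:
    """H-vs-L screening per single feature and for the combined feature set.

    ``pair_features`` is the subjects x features frame from
    :func:`restalpha.association.channel_pair_average`; subjects outside
    groups H and L are ignored.
    """
    groups = groups.reindex(pair_features.index)
    mask = groups.isin(["H", "L"]).to_numpy()
    if groups[mask].nunique() < 2:
        raise ValueError("both H and L groups must be non-empty")
    x_all = pair_features.loc[mask]
    y = groups[mask].to_numpy(dtype=object)

    results = {}
    for feat in pair_features.columns:
        results[feat] = _cv_screen(
            x_all[[feat]].to_numpy(), y, feat, folds, seed, class_weight,
            x_all.index, reps,
        )
    results["combined"] = _cv_screen(
        x_all.to_numpy(), y, "combined", folds, seed, class_weight, x_all.index, reps
    )
    return results


def screen_three_class(
    pair_features: pd.DataFrame,
    groups: pd.Series,
    folds: int = 10,
    seed: int = 0,
    feature_set: str = "combined",
    class_weight=None,
    reps: int = 1,
) -> ScreeningResult:
    """Three-class (H/M/L) screening on the combined (or one) feature set."""
    groups = groups.reindex(pair_features.index)
    mask = groups.isin(GROUP_ORDER).to_numpy()
    y = groups[mask].to_numpy(dtype=object)
    if len(set(y)) < 3:
        raise ValueError("all three groups must be non-empty")
    cols = list(pair_features.columns) if feature_set == "combined" else [feature_set]
    sub = pair_features.loc[mask, cols]
    return _cv_screen(
        sub.to_numpy(), y, feature_set, folds, seed, class_weight, sub.index, reps
    )
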