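"""Motor-imagery performance scoring: one-vs-rest multiclass CSP features,
linear SVM (C=1), repeated stratified 10-fold cross-validation, and the
H/M/L performance grouping.

CSP filters for class c solve the generalized eigenproblem
``S_c w = lambda (S_c + S_rest) w`` on trace-normalized trial covariances,
keeping the eigenvectors of the two largest eigenvalues per class (8 filters
for 4 classes).  Features are the log of each filter's share of the trial
variance.  The spatial filters are refit inside every training fold, so no
test information leaks into the model; a fit-once mode is available for
protocol comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .preprocessing import MI_BAND, MI_CLASSES, TrialSet, bandpass_array

log = logging.getLogger(__name__)

GROUP_THRESHOLDS = (40.0, 60.0)  # accuracy %, boundaries L|M and M|H


@dataclass
class CspModel:
    classes: tuple[str, ...]
    filters: np.ndarray  # (n_classes, n_per_class, n_channels)

    @property
    def filter_matrix(self) -> np.ndarray:
        """All filters stacked, shape (n_classes * n_per_class, n_channels)."""
        return self.filters.reshape(-1, self.filters.shape[-1])


@dataclass
class CvResult:
    mean: float  # accuracy %
    sd: float  # over repetitions, %
    per_rep: np.ndarray


@dataclass
class PerformanceRecord:
    subject_id: str
    acc_4class_mean: float
    acc_4class_sd: float
    acc_lh_rh: float
    acc_hands_feet: float
    group: str


def trial_covariances(trials: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Per-trial spatial covariance X X^T, trace-normalized by default."""
    covs = trials @ trials.transpose(0, 2, 1)
    if normalize:
        traces = np.einsum("ncc->n", covs)
        covs = covs / traces[:, None, None]
    return covs


def _shrink(cov: np.ndarray, lam: float) -> np.ndarray:
    d = cov.shape[0]
    return (1 - lam) * cov + lam * (np.trace(cov) / d) * np.eye(d)


def _class_filters(s_class: np.ndarray, s_rest: np.ndarray, n_per_class: int) -> np.ndarray:
    """Top eigenvectors of the generalized eigenproblem S_c w = l (S_c+S_rest) w."""
    composite = s_class + s_rest
    for lam in (0.0, 1e-10, 1e-6, 1e-3):
        try:
            evals, evecs = scipy.linalg.eigh(_shrink(s_class, lam), _shrink(composite, lam))
            break
        except scipy.linalg.LinAlgError:
            continue
    else:
        raise np.linalg.LinAlgError("singular composite covariance in CSP fit")
    order = np.argsort(evals)[::-1][:n_per_class]
    w = evecs[:, order].T  # (n_per_class, channels)
    # deterministic sign: largest-magnitude coefficient positive
    for row in w:
        imax = int(np.argmax(np.abs(row)))
        if row[imax] < 0:
            row *= -1
    return w


def fit_csp_ovr_cov(
    covs: np.ndarray, labels: np.ndarray, classes: tuple[str, ...], n_per_class: int = 2
) -> CspModel:
    """Fit one-vs-rest CSP from per-trial (trace-normalized) covariances."""
    total = covs.sum(axis=0)
    n = len(covs)
    filters = []
    for cls in classes:
        mask = labels == cls
        k = int(mask.sum())
        if k == 0:
            raise ValueError(f"no trials for class {cls!r}")
        class_sum = covs[mask].sum(axis=0)
        s_class = class_sum / k
        s_rest = (total - class_sum) / (n - k)
        filters.append(_class_filters(s_class, s_rest, n_per_class))
    return CspModel(classes=tuple(classes), filters=np.stack(filters))


def fit_csp_ovr(trials: TrialSet | np.ndarray, labels=None, n_per_class: int = 2) -> CspModel:
    """Fit one-vs-rest multiclass CSP on (band-filtered) trials.

    ``trials`` may be a TrialSet or an (n, channels, samples) array with
    ``labels``.  Warns when a class has fewer trials than channels (noisy
    covariance estimates).
    """
    if isinstance(trials, TrialSet):
        labels = trials.labels
        trials = trials.trials
    labels = np.asarray(labels)
    uniq = list(np.unique(labels))
    if set(uniq) <= set(MI_CLASSES):
        classes = tuple(c for c in MI_CLASSES if c in uniq)
    else:
        classes = tuple(sorted(uniq))
    n_ch = trials.shape[1]
    for cls in classes:
        if (labels == cls).sum() < n_ch:
            warnings.warn(
                f"class {cls!r} has fewer trials than channels ({n_ch}); "
                "covariance estimates will be noisy"
            )
            break
    return fit_csp_ovr_cov(trial_covariances(trials), labels, classes, n_per_class)


def csp_features(trial: np.ndarray, model: CspModel) -> np.ndarray:
    """Normalized log-variance feature vector of one trial (or a trial stack).

    For each spatial filter w: log( var(w^T x) / sum_j var(w_j^T x) ).
    Scale-invariant by construction.
    """
    w = model.filter_matrix
    single = trial.ndim == 2
    x = trial[None] if single else trial
    if x.shape[1] != w.shape[1]:
        raise ValueError("trial channel count does not match the CSP model")
    proj = np.einsum("fc,ncs->nfs", w, x)
    # mean square, not demeaned variance: band-filtered trials are zero-mean
    # and this matches the covariance-based fast path exactly
    var = np.mean(proj * proj, axis=-1)
    total = var.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("zero-variance trial")
    feats = np.log(var / total)
    return feats[0] if single else feats


def csp_features_from_cov(covs: np.ndarray, model: CspModel) -> np.ndarray:
    """Same features computed from per-trial covariances (fast CV path)."""
    w = model.filter_matrix
    var = np.einsum("ncf,fc->nf", covs @ w.T, w)
    var = np.maximum(var, 0.0)
    total = var.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero-variance trial")
    return np.log(np.maximum(var, 1e-300) / total)


def crossval_accuracy(
    trials,
    labels=None,
    folds: int = 10,
    reps: int = 10,
    C: float = 1.0,
    seed: int = 0,
    n_per_class: int = 2,
    refit_csp: bool = True,
) -> CvResult:
    """Repeated stratified k-fold CV of the CSP + linear-SVM classifier.

    CSP is fitted inside each training fold (default) to avoid leaking test
    trials into the spatial filters.  The per-repetition accuracy is the mean
    over folds; returns mean and sd (in %) across repetitions.  Fold
    shuffling uses ``seed + rep``; identical seeds reproduce exactly.
    """
    if isinstance(trials, TrialSet):
        labels = trials.labels
        trials = trials.trials
    labels = np.asarray(labels).astype(str)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} trials, "
            f"fewer than {folds} folds"
        )
    covs = trial_covariances(trials)
    classes = tuple(classes)

    # cohort-scale CV refits CSP per fold; forming each training fold's class
    # covariance as (full class sum) - (small test-fold sum) avoids copying
    # the covariance stack 100 times
    class_masks = {cls: labels == cls for cls in classes}
    full_sums = {cls: covs[m].sum(axis=0) for cls, m in class_masks.items()}
    full_counts = {cls: int(m.sum()) for cls, m in class_masks.items()}

    fit_all = None
    if not refit_csp:
        fit_all = fit_csp_ovr_cov(covs, labels, classes, n_per_class)

    per_rep = np.empty(reps)
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        fold_acc = []
        for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
            if fit_all is not None:
                model = fit_all
            else:
                test_labels = labels[test_idx]
                sums, ns = {}, {}
                for cls in classes:
                    t_idx = test_idx[test_labels == cls]
                    sums[cls] = full_sums[cls] - covs[t_idx].sum(axis=0)
                    ns[cls] = full_counts[cls] - len(t_idx)
                total = sum(sums.values())
                n_train = sum(ns.values())
                filters = [
                    _class_filters(
                        sums[cls] / ns[cls],
                        (total - sums[cls]) / (n_train - ns[cls]),
                        n_per_class,
                    )
                    for cls in classes
                ]
                model = CspModel(classes=classes, filters=np.stack(filters))
            feats = csp_features_from_cov(covs, model)
            clf = SVC(kernel="linear", C=C)
            clf.fit(feats[train_idx], labels[train_idx])
            fold_acc.append(np.mean(clf.predict(feats[test_idx]) == labels[test_idx]))
        per_rep[rep] = 100.0 * np.mean(fold_acc)
    return CvResult(mean=float(per_rep.mean()), sd=float(per_rep.std(ddof=1)) if reps > 1 else 0.0, per_rep=per_rep)


def assign_group(acc_4class_mean: float) -> str:
    """H/M/L performance group from the mean 4-class accuracy (%).

    Boundaries: accuracy >= 60 -> H, 40 <= accuracy < 60 -> M, < 40 -> L.
    """
    if not 0 <= acc_4class_mean <= 100:
        raise ValueError("accuracy must be a percentage in [0, 100]")
    lo, hi = GROUP_THRESHOLDS
    if acc_4class_mean >= hi:
        return "H"
    if acc_4class_mean >= lo:
        return "M"
    return "L"


def score_subject(
    trial_set: TrialSet,
    folds: int = 10,
    reps: int = 10,
    C: float = 1.0,
    seed: int = 0,
    filter_order: int = 4,
    prefiltered: bool = False,
) -> PerformanceRecord:
    """Full MI-performance record for one subject.

    Trials are band-filtered to 8-30 Hz (unless ``prefiltered``), then the
    4-class problem and the two 2-class problems (left vs right hand, both
    hands vs feet) are cross-validated.
    """
    trials = trial_set.trials
    if not prefiltered:
        # float32 filtering: halves the dominant cost; covariances and the
        # classifier are insensitive at this precision
        trials = bandpass_array(
            trial_set.trials.astype(np.float32), trial_set.sample_rate, MI_BAND, filter_order
        ).astype(np.float64)
    labels = trial_set.labels.astype(str)

    cv4 = crossval_accuracy(trials, labels, folds, reps, C, seed)

    def two_class(a: str, b: str) -> float:
        mask = (labels == a) | (labels == b)
        return crossval_accuracy(trials[mask], labels[mask], folds, reps, C, seed).mean

    return PerformanceRecord(
        subject_id=trial_set.subject_id,
        acc_4class_mean=cv4.mean,
        acc_4class_sd=cv4.sd,
        acc_lh_rh=two_class("left_hand", "right_hand"),
        acc_hands_feet=two_class("both_hands", "feet"),
        group=assign_group(cv4.mean),
    )
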