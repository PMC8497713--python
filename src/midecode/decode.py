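"""Shrinkage-LDA classification and cross-validated accuracy time courses.

Linear discriminant analysis with analytic (Ledoit–Wolf) shrinkage of the
pooled covariance toward a scaled identity is the workhorse classifier for
all three decoding problems: movement direction (right vs. up), motor imagery
vs. baseline, and guidance condition. Accuracies are estimated with repeated
stratified cross-validation over trials — folds never split within a trial —
and summarized as a time course with its better-than-chance threshold and
peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.model_selection import StratifiedKFold

from .features import BandPowerFeatureSet, SlidingFeatureSet
from . import stats as mstats


@dataclass
class ShrinkageLDAModel:
    """Binary sLDA: decision d(x) = wᵀx + b, positive ⇒ first class.

    The pooled within-class covariance Σ is regularized as
    (1-λ)Σ + λνI with ν = trace(Σ)/p (the average eigenvalue), and
    w = Σ_reg⁻¹(μ₁-μ₂); the bias places the boundary midway between the
    projected class means (equal priors — the paradigm balances classes).
    """

    weights: np.ndarray
    bias: float
    shrinkage: float
    class_means: np.ndarray  # (2, n_features)
    pooled_cov: np.ndarray
    classes: tuple

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision(X)
        return np.where(d > 0, self.classes[0], self.classes[1])


def fit_slda(
    X: np.ndarray, y: np.ndarray, shrinkage: Optional[float] = None
) -> ShrinkageLDAModel:
    """Fit binary shrinkage LDA.

    When ``shrinkage`` is None the intensity λ ∈ [0, 1] is estimated with the
    Ledoit–Wolf closed form on class-centered samples (deterministic, no CV).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    mus = np.array([X[y == c].mean(axis=0) for c in classes])
    centered = np.concatenate([X[y == c] - mus[i] for i, c in enumerate(classes)])
    n, p = centered.shape
    pooled = (centered.T @ centered) / n
    if shrinkage is None:
        shrinkage = float(ledoit_wolf_shrinkage(centered, assume_centered=True))
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    nu = np.trace(pooled) / p
    reg = (1.0 - shrinkage) * pooled + shrinkage * nu * np.eye(p)
    diff = mus[0] - mus[1]
    w = np.linalg.solve(reg, diff)
    b = -0.5 * float(w @ (mus[0] + mus[1]))
    return ShrinkageLDAModel(
        weights=w,
        bias=b,
        shrinkage=shrinkage,
        class_means=mus,
        pooled_cov=pooled,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CvScheme:
    """Repeated stratified k-fold over trials."""

    n_folds: int = 5
    n_repeats: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def splits(self, y: np.ndarray):
        """Yield (train_idx, test_idx) over all repeats."""
        y = np.asarray(y)
        for r in range(self.n_repeats):
            cv = StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.seed + r
            )
            yield from cv.split(np.zeros(len(y)), y)


@dataclass
class AccuracyTimecourse:
    """Per-timepoint cross-validated accuracy with its chance threshold."""

    times: np.ndarray
    accuracy_pct: np.ndarray
    n_trials_effective: int
    threshold_pct: float
    peak: tuple[float, float] = field(default=(np.nan, np.nan))  # (time, pct)


#: Per-fold feature builder: maps training-trial indices to the full
#: (trials x timepoints x features) tensor, with every *fitted* step (e.g.,
#: CSP) estimated on the training trials only. Keeping supervised feature
#: extraction inside the fold is what makes the null calibration honest —
#: spatial filters fit on all trials leak label information into the test set.
FeatureBuilder = Callable[[np.ndarray], np.ndarray]


def _cv_accuracy_matrix(
    get_X: FeatureBuilder,
    y: np.ndarray,
    scheme: CvScheme,
    shrinkage: Optional[float] = None,
) -> np.ndarray:
    """Accuracy per timepoint, averaged over folds then repeats."""
    y = np.asarray(y)
    accs = None
    n_splits = 0
    for train, test in scheme.splits(y):
        if len(np.unique(y[train])) < 2:
            raise ValueError("a training fold contains a single class")
        X = get_X(train)
        if accs is None:
            accs = np.zeros(X.shape[1])
        for t in range(X.shape[1]):
            model = fit_slda(X[train, t, :], y[train], shrinkage=shrinkage)
            accs[t] += np.mean(model.predict(X[test, t, :]) == y[test])
        n_splits += 1
    return 100.0 * accs / n_splits


def sliding_accuracy(
    features: Union[SlidingFeatureSet, BandPowerFeatureSet],
    labels: np.ndarray,
    scheme: CvScheme,
    alpha: float = 0.05,
    search_window_s: Optional[tuple[float, float]] = None,
) -> AccuracyTimecourse:
    """Cross-validated accuracy at every feature timepoint.

    One label per trial; the classifier is re-trained per timepoint on the
    training trials' features at that timepoint only.
    """
    labels = np.asarray(labels)
    if len(labels) != features.features.shape[0]:
        raise ValueError("one label per trial required")
    return sliding_accuracy_refit(
        lambda train: features.features,
        features.timepoints,
        labels,
        scheme,
        alpha=alpha,
        search_window_s=search_window_s,
    )


def sliding_accuracy_refit(
    feature_builder: FeatureBuilder,
    timepoints: np.ndarray,
    labels: np.ndarray,
    scheme: CvScheme,
    alpha: float = 0.05,
    search_window_s: Optional[tuple[float, float]] = None,
) -> AccuracyTimecourse:
    """Sliding accuracy with per-fold feature refitting (see FeatureBuilder)."""
    labels = np.asarray(labels)
    acc = _cv_accuracy_matrix(feature_builder, labels, scheme)
    thr = mstats.chance_threshold(len(labels), 2, alpha).threshold_pct
    tc = AccuracyTimecourse(
        times=np.asarray(timepoints, dtype=float).copy(),
        accuracy_pct=acc,
        n_trials_effective=len(labels),
        threshold_pct=thr,
    )
    window = search_window_s or (float(tc.times[0]), float(tc.times[-1]) + 1e-9)
    tc.peak = peak_accuracy(tc, window)
    return tc


def _features_at(feats, time_s: float) -> np.ndarray:
    """Feature matrix (trials x features) at the timepoint nearest ``time_s``."""
    k = int(np.argmin(np.abs(feats.timepoints - time_s)))
    return feats.features[:, k, :]


def fixed_window_accuracy(
    epoch_features: Union[SlidingFeatureSet, BandPowerFeatureSet],
    labels: Optional[np.ndarray],
    mi_window_s: tuple[float, float] = (0.5, 1.5),
    baseline_window_s: tuple[float, float] = (-3.5, -2.5),
    scheme: CvScheme = CvScheme(),
    alpha: float = 0.05,
) -> AccuracyTimecourse:
    """MI-vs-baseline classification from two fixed windows.

    Each trial contributes one MI sample (the causal feature vector at the MI
    window's right edge, which spans exactly that window) and one baseline
    sample; cross-validation folds split trials, keeping a trial's two samples
    on the same side of the split. ``labels`` (the trial class labels) are
    ignored here — the classes are the windows themselves.
    """
    return fixed_window_accuracy_refit(
        lambda train: epoch_features.features,
        epoch_features.timepoints,
        epoch_features.features.shape[0],
        mi_window_s,
        baseline_window_s,
        scheme,
        alpha=alpha,
    )


def fixed_window_accuracy_refit(
    feature_builder: FeatureBuilder,
    timepoints: np.ndarray,
    n_trials: int,
    mi_window_s: tuple[float, float] = (0.5, 1.5),
    baseline_window_s: tuple[float, float] = (-3.5, -2.5),
    scheme: CvScheme = CvScheme(),
    alpha: float = 0.05,
) -> AccuracyTimecourse:
    """MI-vs-baseline accuracy with per-fold feature refitting."""
    if mi_window_s[0] < baseline_window_s[1] and baseline_window_s[0] < mi_window_s[1]:
        raise ValueError("MI and baseline windows overlap")
    timepoints = np.asarray(timepoints, dtype=float)
    k_mi = int(np.argmin(np.abs(timepoints - mi_window_s[1])))
    k_base = int(np.argmin(np.abs(timepoints - baseline_window_s[1])))
    accs = []
    n = n_trials
    for r in range(scheme.n_repeats):
        rng = np.random.default_rng(scheme.seed + r)
        order = rng.permutation(n)
        for test in np.array_split(order, scheme.n_folds):
            train = np.setdiff1d(order, test)
            X = feature_builder(train)
            x_mi, x_base = X[:, k_mi, :], X[:, k_base, :]
            X_tr = np.concatenate([x_mi[train], x_base[train]])
            y_tr = np.array(["MI"] * len(train) + ["baseline"] * len(train))
            X_te = np.concatenate([x_mi[test], x_base[test]])
            y_te = np.array(["MI"] * len(test) + ["baseline"] * len(test))
            model = fit_slda(X_tr, y_tr)
            accs.append(np.mean(model.predict(X_te) == y_te))
    acc_pct = 100.0 * float(np.mean(accs))
    thr = mstats.chance_threshold(2 * n, 2, alpha).threshold_pct
    t_mi = float(mi_window_s[1])
    return AccuracyTimecourse(
        times=np.array([t_mi]),
        accuracy_pct=np.array([acc_pct]),
        n_trials_effective=2 * n,
        threshold_pct=thr,
        peak=(t_mi, acc_pct),
    )


def peak_accuracy(
    tc: AccuracyTimecourse, search_window_s: tuple[float, float]
) -> tuple[float, float]:
    """Maximum accuracy and its time inside the window; ties -> earliest."""
    lo, hi = search_window_s
    mask = (tc.times >= lo - 1e-9) & (tc.times <= hi + 1e-9)
    if not np.any(mask):
        raise ValueError(f"search window {search_window_s} contains no timepoints")
    times = tc.times[mask]
    accs = tc.accuracy_pct[mask]
    i = int(np.argmax(accs))  # argmax returns the first maximum: earliest time
    return float(times[i]), float(accs[i])
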