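"""Classifiers, leak-free cross-validation and confusion-matrix metrics.

Three classifiers operate on the fused log-variance feature vector: an
RBF-kernel SVM (default; width from the median pairwise training
distance), LDA with a small pooled-covariance ridge, and a small
feed-forward network (one sigmoid hidden layer of 10 units, linear
two-unit output, full-batch quasi-Newton training).

Evaluation is stratified k-fold (k=5 by default) over trials.  All
data-dependent fitting — entropy channel ranking, CSP filters, the
classifier — happens on the training partition only; test trials are
merely transformed and scored.  A ``leaky_selection`` switch ranks
channels on the whole dataset instead, reproducing the common
whole-dataset selection protocol for comparison.

Metrics follow the usual confusion-matrix definitions with class 1 as
positive:

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Zero-denominator ratios are reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .config import ClassifierSpec, PipelineConfig
from .csp import extract_features, fit_multiband
from .entropy_select import channel_entropy, rank_channels
from .exceptions import StratificationError, ValidationError
from .filterbank import FilterBankSpec, apply_filterbank
from .io_formats import EpochedEEG
from .preprocess import BandpassSpec, bandpass

__all__ = [
    "Metrics",
    "EvalReport",
    "confusion_metrics",
    "train_classifier",
    "cross_validate",
]


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    undefined: tuple = ()  # metric names whose denominator was zero

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "undefined": list(self.undefined),
        }


@dataclass
class EvalReport:
    """Per-fold metrics, their means/stds, and the resolved configuration."""

    folds: list
    mean: dict
    std: dict
    config: dict
    selected_channels: list  # per fold: channel names kept, ranked

    def to_dict(self) -> dict:
        return {
            "folds": [m.to_dict() for m in self.folds],
            "mean": self.mean,
            "std": self.std,
            "config": self.config,
            "selected_channels": self.selected_channels,
        }


def confusion_metrics(y_true, y_pred) -> Metrics:
    """Accuracy/precision/recall/F1 from labels over {1, 2}; 1 is positive."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValidationError("label vectors must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        bad = set(y) - {1, 2}
        if bad:
            raise ValidationError(f"{name} contains labels outside {{1, 2}}: {sorted(bad)}")

    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 2)))
    fp = int(np.sum((y_true == 2) & (y_pred == 1)))
    tn = int(np.sum((y_true == 2) & (y_pred == 2)))

    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = ratio(tp + tn, tp + fp + tn + fn, "accuracy")
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    return Metrics(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        tp=tp, fp=fp, tn=tn, fn=fn, undefined=tuple(undefined),
    )


def _median_gamma(x: np.ndarray) -> float:
    d = pdist(x)
    med = np.median(d[d > 0]) if np.any(d > 0) else 0.0
    if med == 0:
        return 1.0 / max(x.shape[1], 1)  # degenerate features: fall back
    return 1.0 / (2.0 * med**2)


def train_classifier(x: np.ndarray, y: np.ndarray, spec: Optional[ClassifierSpec] = None, seed: int = 0):
    """Fit the classifier of *spec* on features x (M x D), labels y in {1,2}."""
    spec = spec or ClassifierSpec()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y).ravel()
    if not np.all(np.isfinite(x)):
        raise ValidationError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("training data must contain both classes")

    if spec.kind == "svm_rbf":
        gamma = _median_gamma(x) if spec.gamma == "median" else float(spec.gamma)
        model = SVC(C=spec.c, kernel="rbf", gamma=gamma)
    elif spec.kind == "lda":
        model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=spec.lda_ridge)
    else:  # ann
        model = MLPClassifier(
            hidden_layer_sizes=(spec.hidden_size,),
            activation="logistic",
            solver="lbfgs",
            max_iter=spec.max_epochs,
            random_state=seed,
        )
    model.fit(x, y)
    return model


def _prepare(epoched: EpochedEEG, cfg: PipelineConfig):
    """Broadband-filter once and pre-compute all-channel sub-band layers.

    Both stages are per-trial, per-channel linear maps with no
    cross-trial fitting, so computing them before the fold split cannot
    leak test-trial information into training.
    """
    broadband = bandpass(
        epoched,
        BandpassSpec(
            low_hz=cfg.broadband_low_hz,
            high_hz=cfg.broadband_high_hz,
            order=cfg.broadband_order,
        ),
    )
    subbands = apply_filterbank(
        broadband, FilterBankSpec(bands=cfg.bands, order=cfg.filterbank_order)
    )
    return broadband, subbands


def _slice_epoched(e: EpochedEEG, idx: np.ndarray) -> EpochedEEG:
    return EpochedEEG(
        data=e.data[idx], fs=e.fs, channel_names=list(e.channel_names), labels=e.labels[idx]
    )


def cross_validate(
    epoched: EpochedEEG,
    cfg: Optional[PipelineConfig] = None,
    n_folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold evaluation of the full pipeline.

    Per fold: entropy ranking and top-k selection fitted on training
    trials, per-band CSP fitted on training trials, classifier trained
    on training features; the held-out fold is transformed with the
    fitted objects and scored.  ``n_folds`` may equal the trial count
    (leave-one-out).
    """
    cfg = cfg or PipelineConfig()
    m, l = epoched.n_trials, epoched.n_channels
    if m < n_folds:
        raise ValidationError(f"need at least n_folds={n_folds} trials, got {m}")
    k = cfg.n_select if cfg.n_select is not None else l
    if not 1 <= k <= l:
        raise ValidationError(f"n_select must be in [1, {l}], got {k}")
    # 2V filters cannot exceed the selected channel count; clamp the pair
    # count so small-k sweeps stay well-posed
    v_eff = min(cfg.csp_pairs, k // 2)
    if v_eff < 1:
        raise ValidationError(f"need at least 2 selected channels for CSP, got k={k}")

    broadband, subbands = _prepare(epoched, cfg)

    global_ranking = None
    if cfg.leaky_selection:
        global_ranking = rank_channels(
            channel_entropy(
                broadband, bins=cfg.entropy_bins,
                literal_sample_sum=cfg.entropy_literal_sample_sum,
            )
        )

    # stratified folds keep class proportions; when n_folds exceeds the
    # minority-class count (e.g. leave-one-out) fall back to plain k-fold
    min_class = int(np.min(np.unique(epoched.labels, return_counts=True)[1]))
    if n_folds <= min_class:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds, selected = [], []
    for fold_i, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(m), epoched.labels)):
        y_train = epoched.labels[train_idx]
        if len(set(y_train)) < 2:
            raise StratificationError(f"fold {fold_i}: a class is absent from training")

        if global_ranking is not None:
            ranking = global_ranking
        else:
            ranking = rank_channels(
                channel_entropy(
                    _slice_epoched(broadband, train_idx),
                    bins=cfg.entropy_bins,
                    literal_sample_sum=cfg.entropy_literal_sample_sum,
                )
            )
        chan_idx = ranking.order[:k]
        sub_train = subbands.select_channels(chan_idx)
        sub_train = type(sub_train)(
            data=sub_train.data[:, train_idx], spec=sub_train.spec, fs=sub_train.fs,
            channel_names=sub_train.channel_names, labels=epoched.labels[train_idx],
        )
        sub_test_full = subbands.select_channels(chan_idx)
        sub_test = type(sub_test_full)(
            data=sub_test_full.data[:, test_idx], spec=sub_test_full.spec, fs=sub_test_full.fs,
            channel_names=sub_test_full.channel_names, labels=epoched.labels[test_idx],
        )

        model = fit_multiband(sub_train, v=v_eff, reg=cfg.csp_reg)
        feat_train = extract_features(sub_train, model, cfg.normalized_variance)
        feat_test = extract_features(sub_test, model, cfg.normalized_variance)

        clf = train_classifier(feat_train.values, y_train, cfg.classifier, seed=seed)
        y_pred = clf.predict(feat_test.values)
        folds.append(confusion_metrics(epoched.labels[test_idx], y_pred))
        selected.append([epoched.channel_names[i] for i in chan_idx])

    names = ("accuracy", "precision", "recall", "f1")
    mean = {n: float(np.mean([getattr(f, n) for f in folds])) for n in names}
    std = {n: float(np.std([getattr(f, n) for f in folds])) for n in names}
    config = cfg.to_dict()
    config.update({"n_folds": n_folds, "seed": seed, "n_select_effective": int(k)})
    return EvalReport(folds=folds, mean=mean, std=std, config=config, selected_channels=selected)
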