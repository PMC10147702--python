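"""SVM scoring of peak-groups and target/decoy FDR estimation.

An RBF-kernel support vector machine is trained on the seven descriptors of
the labelled training set (targets = positive class, decoys = negative).
Descriptors are standardised to zero mean and unit variance using the
training statistics; the calibrated target-class probability — obtained by
a maximum-likelihood sigmoid fit to the SVM decision values — is the score
of a peak-group.  Scanning the observed scores as thresholds and counting
targets (TP) and decoys (FP) above each yields the FDR = FP / (TP + FP)
estimate, tabulated as (score threshold, FDR) pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import N_DESCRIPTORS
from .core_model import DECOY, TARGET
from .descriptors import DESCRIPTOR_NAMES, ScoreVector

log = logging.getLogger("peakdecoder.classifier")

MODEL_FORMAT_VERSION = 1


@dataclass
class TrainedModel:
    """A fitted scaler + SVM with its cross-validation accuracy."""

    scaler_mean: np.ndarray  # per-descriptor training means
    scaler_sd: np.ndarray    # per-descriptor training standard deviations
    svm: SVC
    cv_accuracy: float       # mean 10-fold CV accuracy, percent
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.scaler_mean) != N_DESCRIPTORS or len(self.scaler_sd) != N_DESCRIPTORS:
            raise ValueError(f"scaler must have exactly {N_DESCRIPTORS} entries")
        if not 0.0 <= self.cv_accuracy <= 100.0:
            raise ValueError("cv_accuracy must be a percentage")


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts at one score threshold; targets are the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class FDRTableRow:
    score_threshold: float
    fdr: float


def _design_matrix(vectors: list[tuple[ScoreVector, str]]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Stack labelled vectors, rejecting rows with non-finite descriptors."""
    rows, labels = [], []
    n_rejected = 0
    for v, label in vectors:
        arr = v.as_array()
        if not np.all(np.isfinite(arr)):
            n_rejected += 1
            continue
        rows.append(arr)
        labels.append(1 if label == TARGET else 0)
    if n_rejected:
        log.warning("train: rejected %d rows with non-finite descriptors", n_rejected)
    if not rows:
        raise ValueError("no usable training vectors")
    return np.vstack(rows), np.asarray(labels)


def train(vectors: list[tuple[ScoreVector, str]], seed: int = 0,
          cost: float = 1.0, gamma: float | None = None,
          cv_folds: int = 10) -> TrainedModel:
    """Train the binary target/decoy classifier.

    Descriptors are standardised; the SVM uses a radial (RBF) kernel with
    ``gamma`` defaulting to 1/7 (one over the number of descriptors) and
    probability calibration enabled.  ``cv_accuracy`` is the mean accuracy
    over seeded stratified 10-fold cross-validation, in percent.  Fewer
    than 50 vectors in either class triggers a warning: small training
    sets give unreliable FDR estimates.
    """
    if gamma is None:
        gamma = 1.0 / N_DESCRIPTORS
    X, y = _design_matrix(vectors)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training requires both target and decoy vectors")
    if min(n_pos, n_neg) < 50:
        log.warning("train: only %d targets / %d decoys — too few for a "
                    "reliable FDR estimate", n_pos, n_neg)

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)

    svm = SVC(kernel="rbf", C=cost, gamma=gamma, probability=True,
              random_state=seed)
    with warnings.catch_warnings():
        # sklearn 1.9 deprecates probability=True in favour of
        # CalibratedClassifierCV; the built-in Platt fit on decision values
        # is exactly the calibration wanted here
        warnings.simplefilter("ignore", FutureWarning)
        svm.fit(Xs, y)

    folds = min(cv_folds, n_pos, n_neg)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_pipeline = make_pipeline(
        StandardScaler(), SVC(kernel="rbf", C=cost, gamma=gamma))
    fold_acc = cross_val_score(cv_pipeline, X, y, cv=cv, scoring="accuracy")
    cv_accuracy = float(fold_acc.mean() * 100.0)

    log.info("train: %d targets, %d decoys, CV accuracy %.2f%%",
             n_pos, n_neg, cv_accuracy)
    return TrainedModel(
        scaler_mean=scaler.mean_.copy(),
        scaler_sd=scaler.scale_.copy(),
        svm=svm, cv_accuracy=cv_accuracy, seed=seed,
        params={"kernel": "rbf", "C": cost, "gamma": gamma,
                "cv_folds": folds, "descriptors": list(DESCRIPTOR_NAMES)})


def _target_column(model: TrainedModel) -> int:
    return int(np.where(model.svm.classes_ == 1)[0][0])


def score_many(model: TrainedModel, vectors: list[ScoreVector]) -> np.ndarray:
    """Calibrated target-class probabilities for a batch of vectors."""
    X = np.vstack([v.as_array() for v in vectors])
    Xs = (X - model.scaler_mean) / model.scaler_sd
    return model.svm.predict_proba(Xs)[:, _target_column(model)]


def score(model: TrainedModel, v: ScoreVector) -> float | None:
    """The peak-group score: calibrated probability of being a true group.

    Returns ``None`` (missing, never 0) for a vector with non-finite
    descriptors.
    """
    arr = v.as_array()
    if not np.all(np.isfinite(arr)):
        log.warning("score: unscorable vector (non-finite descriptor)")
        return None
    return float(score_many(model, [v])[0])


def compute_fdr(c: ConfusionCounts) -> float:
    """FDR = FP / (TP + FP); zero when there are no discoveries."""
    if c.tp + c.fp == 0:
        return 0.0
    return c.fp / (c.tp + c.fp)


def confusion_at_threshold(scores: np.ndarray, labels: np.ndarray,
                           threshold: float) -> ConfusionCounts:
    """Counts when classifying ``score > threshold`` as target."""
    pred = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)), fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)), fn=int(np.sum(~pred & pos)))


def build_fdr_table(model: TrainedModel,
                    vectors: list[tuple[ScoreVector, str]]) -> list[FDRTableRow]:
    """The (score threshold, FDR) table from the labelled training set.

    Candidate thresholds are all distinct observed scores, descending.  Raw
    FDR values are made monotone (non-decreasing as the threshold drops) by
    taking, at each threshold, the minimum FDR attainable at that or any
    lower threshold — the standard q-value-style envelope, which makes the
    FDR -> score lookup well-defined.
    """
    X_labels = [(v, lab) for v, lab in vectors]
    scores = score_many(model, [v for v, _ in X_labels])
    labels = np.asarray([1 if lab == TARGET else 0 for _, lab in X_labels])
    thresholds = np.unique(scores)[::-1]  # descending
    raw = np.array([compute_fdr(confusion_at_threshold(scores, labels, t))
                    for t in thresholds])
    # suffix minimum: envelope over this-or-lower thresholds
    enveloped = np.minimum.accumulate(raw[::-1])[::-1]
    return [FDRTableRow(score_threshold=float(t), fdr=float(f))
            for t, f in zip(thresholds, enveloped)]


def threshold_for_fdr(table: list[FDRTableRow], target_fdr: float = 0.01
                      ) -> float | None:
    """Smallest score threshold whose enveloped FDR is at or below target.

    When the target is unreachable, logs the minimum attainable non-zero
    FDR and returns ``None``.
    """
    eligible = [row.score_threshold for row in table if row.fdr <= target_fdr]
    if eligible:
        return min(eligible)
    nonzero = [row.fdr for row in table if row.fdr > 0]
    if nonzero:
        log.warning("threshold_for_fdr: FDR %.3g unreachable; minimum "
                    "non-zero estimated FDR is %.3g", target_fdr, min(nonzero))
    return None


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist the model to a single versioned archive file."""
    payload = {"format_version": MODEL_FORMAT_VERSION,
               "scaler_mean": model.scaler_mean, "scaler_sd": model.scaler_sd,
               "svm": model.svm, "cv_accuracy": model.cv_accuracy,
               "seed": model.seed, "params": model.params}
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {version!r}")
    return TrainedModel(
        scaler_mean=payload["scaler_mean"], scaler_sd=payload["scaler_sd"],
        svm=payload["svm"], cv_accuracy=payload["cv_accuracy"],
        seed=payload["seed"], params=payload["params"])
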