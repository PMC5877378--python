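"""The three classification protocols and their evaluation metrics.

All protocols are subject-dependent and use a linear-kernel SVM with the
library default regularization, features z-scored with training-fold
statistics only:

* binary leave-one-clip-out — joy clips versus the four negative-emotion
  clip groups (neutral excluded; 15 eligible clips, so each fold trains
  on 14 clips and tests on the held-out one),
* six-class clip-position cross-validation — three folds, each testing
  one clip per emotion and training on the other two,
* cross-paradigm transfer — train on all movie epochs, test on all
  recall epochs (binary variant restricted to the 15 eligible clips on
  both sides).

Folds are split by clip, never by epoch, so temporally correlated epochs
from one clip cannot leak between train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import feature_columns


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class ProtocolSpec:
    task: str = "within_movie"  # within_movie | within_recall | cross_paradigm
    scheme: str = "binary"  # binary | six_class
    positive: tuple[str, ...] = ("joy",)
    negative: tuple[str, ...] = ("sad", "disgust", "anger", "fear")
    excluded: tuple[str, ...] = ("neutral",)

    def __post_init__(self) -> None:
        if self.task not in ("within_movie", "within_recall", "cross_paradigm"):
            raise ProtocolError(f"unknown task {self.task!r}")
        if self.scheme not in ("binary", "six_class"):
            raise ProtocolError(f"unknown scheme {self.scheme!r}")


@dataclass
class SubjectResult:
    """Per-subject protocol outcome: fold accuracies and pooled counts."""

    subject: str
    fold_accuracies: list[float]  # percent
    confusion: pd.DataFrame  # predicted x true counts
    scores: np.ndarray | None = None  # pooled decision values (binary)
    score_labels: np.ndarray | None = None  # +1 positive / -1 negative
    fold_train_sizes: list[int] = field(default_factory=list)
    fold_test_sizes: list[int] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        """Subject accuracy: mean of fold accuracies, percent."""
        return float(np.mean(self.fold_accuracies))


def _svm():
    # linear kernel, default C — mirroring a stock LIBSVM configuration;
    # z-scoring uses training statistics only because it sits in the pipeline
    return make_pipeline(StandardScaler(), SVC(kernel="linear"))


def _empty_confusion(classes: list[str]) -> pd.DataFrame:
    z = np.zeros((len(classes), len(classes)), dtype=int)
    return pd.DataFrame(z, index=classes, columns=classes)


def _accumulate(conf: pd.DataFrame, y_true, y_pred) -> None:
    for t, p in zip(y_true, y_pred):
        conf.loc[p, t] += 1


def _binary_frame(frame: pd.DataFrame, spec: ProtocolSpec) -> pd.DataFrame:
    eligible = frame["emotion"].isin(spec.positive + spec.negative)
    return frame.loc[eligible]


def _binary_labels(emotions: pd.Series, spec: ProtocolSpec) -> np.ndarray:
    return np.where(emotions.isin(spec.positive), "positive", "negative")


def binary_leave_one_clip_out(
    frame: pd.DataFrame, spec: ProtocolSpec | None = None, cols: list[str] | None = None
) -> SubjectResult:
    """Leave-one-clip-out binary protocol for one subject and paradigm.

    With 3 positive and 12 negative clips of 49 epochs each this yields 15
    folds of 686 train / 49 test epochs; the subject accuracy is the mean
    of the fold accuracies.
    """
    spec = spec or ProtocolSpec()
    cols = cols or feature_columns(frame)
    sub = _binary_frame(frame, spec)
    expected = {
        cid
        for cid, emo in sub.groupby("clip_id")["emotion"].first().items()
    }
    needed_emotions = set(spec.positive + spec.negative)
    present_emotions = set(sub["emotion"])
    if present_emotions != needed_emotions:
        raise ProtocolError(
            f"missing emotions {sorted(needed_emotions - present_emotions)}"
        )
    X = sub[cols].to_numpy()
    y = _binary_labels(sub["emotion"], spec)
    clips = sub["clip_id"].to_numpy()

    conf = _empty_confusion(["positive", "negative"])
    fold_acc: list[float] = []
    train_sizes: list[int] = []
    test_sizes: list[int] = []
    scores: list[np.ndarray] = []
    score_labels: list[np.ndarray] = []
    for clip in sorted(expected):
        test = clips == clip
        if not test.any():
            raise ProtocolError(f"clip {clip} has no epochs")
        model = _svm().fit(X[~test], y[~test])
        pred = model.predict(X[test])
        fold_acc.append(100.0 * np.mean(pred == y[test]))
        train_sizes.append(int((~test).sum()))
        test_sizes.append(int(test.sum()))
        _accumulate(conf, y[test], pred)
        # decision_function sign convention: positive class is the
        # lexicographically later label ("positive" > "negative")
        scores.append(model.decision_function(X[test]))
        score_labels.append(np.where(y[test] == "positive", 1, -1))
    subject = str(frame["subject"].iloc[0]) if "subject" in frame else "?"
    return SubjectResult(
        subject=subject,
        fold_accuracies=fold_acc,
        confusion=conf,
        scores=np.concatenate(scores),
        score_labels=np.concatenate(score_labels),
        fold_train_sizes=train_sizes,
        fold_test_sizes=test_sizes,
    )


def six_class_cv(
    frame: pd.DataFrame, cols: list[str] | None = None, n_folds: int | None = None
) -> SubjectResult:
    """Clip-position cross-validation over all six emotions.

    Clips of each emotion are ordered by id; fold f tests the f-th clip of
    every emotion (6 clips) and trains on the remaining ones.  With 3 clips
    per emotion and 49 epochs per clip: 3 folds, 588 train / 294 test.
    """
    cols = cols or feature_columns(frame)
    clip_emotion = frame.groupby("clip_id")["emotion"].first()
    by_emotion: dict[str, list[int]] = {}
    for cid, emo in clip_emotion.items():
        by_emotion.setdefault(emo, []).append(cid)
    counts = {e: len(c) for e, c in by_emotion.items()}
    if n_folds is None:
        n_folds = min(counts.values())
    if len(set(counts.values())) != 1:
        raise ProtocolError(f"unbalanced clips per emotion: {counts}")

    classes = sorted(by_emotion)
    X = frame[cols].to_numpy()
    y = frame["emotion"].to_numpy()
    clips = frame["clip_id"].to_numpy()

    conf = _empty_confusion(classes)
    fold_acc: list[float] = []
    train_sizes: list[int] = []
    test_sizes: list[int] = []
    for f in range(n_folds):
        test_clips = {sorted(cids)[f] for cids in by_emotion.values()}
        test = np.isin(clips, list(test_clips))
        model = _svm().fit(X[~test], y[~test])
        pred = model.predict(X[test])
        fold_acc.append(100.0 * np.mean(pred == y[test]))
        train_sizes.append(int((~test).sum()))
        test_sizes.append(int(test.sum()))
        _accumulate(conf, y[test], pred)
    subject = str(frame["subject"].iloc[0]) if "subject" in frame else "?"
    return SubjectResult(
        subject=subject,
        fold_accuracies=fold_acc,
        confusion=conf,
        fold_train_sizes=train_sizes,
        fold_test_sizes=test_sizes,
    )


def cross_paradigm(
    movie: pd.DataFrame,
    recall: pd.DataFrame,
    scheme: str = "six_class",
    spec: ProtocolSpec | None = None,
    cols: list[str] | None = None,
) -> SubjectResult:
    """Train on the movie paradigm, test on the recall paradigm (one fold).

    The binary variant restricts both sides to the eligible (positive +
    negative) clips.
    """
    spec = spec or ProtocolSpec(task="cross_paradigm", scheme=scheme)
    cols = cols or feature_columns(movie)
    if set(movie["clip_id"]) != set(recall["clip_id"]):
        raise ProtocolError("movie and recall paradigms cover different clips")
    if scheme == "binary":
        movie = _binary_frame(movie, spec)
        recall = _binary_frame(recall, spec)
        y_train = _binary_labels(movie["emotion"], spec)
        y_test = _binary_labels(recall["emotion"], spec)
        classes = ["positive", "negative"]
    else:
        y_train = movie["emotion"].to_numpy()
        y_test = recall["emotion"].to_numpy()
        classes = sorted(set(y_train))
    model = _svm().fit(movie[cols].to_numpy(), y_train)
    Xt = recall[cols].to_numpy()
    pred = model.predict(Xt)
    conf = _empty_confusion(classes)
    _accumulate(conf, y_test, pred)
    acc = 100.0 * np.mean(pred == y_test)
    scores = score_labels = None
    if scheme == "binary":
        scores = model.decision_function(Xt)
        score_labels = np.where(y_test == "positive", 1, -1)
    subject = str(movie["subject"].iloc[0]) if "subject" in movie else "?"
    return SubjectResult(
        subject=subject,
        fold_accuracies=[float(acc)],
        confusion=conf,
        scores=scores,
        score_labels=score_labels,
        fold_train_sizes=[len(movie)],
        fold_test_sizes=[len(recall)],
    )


def metrics_from_confusion(matrix) -> dict:
    """Accuracy and per-class precision/recall/F1 from a predicted x true
    count matrix (rows = predicted, columns = true)."""
    if isinstance(matrix, pd.DataFrame):
        classes = list(matrix.columns)
        M = matrix.to_numpy(dtype=float)
    else:
        M = np.asarray(matrix, dtype=float)
        classes = [str(i) for i in range(M.shape[0])]
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (M < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    total = M.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zeros")
    accuracy = 100.0 * np.trace(M) / total
    per_class = {}
    for i, c in enumerate(classes):
        tp = M[i, i]
        predicted = M[i, :].sum()
        actual = M[:, i].sum()
        precision = tp / predicted if predicted else 0.0
        recall = tp / actual if actual else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[c] = {"precision": precision, "recall": recall, "f1": f1}
    return {"accuracy": accuracy, "per_class": per_class}


def roc_curve_points(scores: np.ndarray, labels: np.ndarray):
    """ROC points from decision values; labels are +1/-1 (or truthy positive).

    Thresholds sweep the unique scores from high to low; returns (fpr, tpr)
    arrays starting at (0, 0) and ending at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) > 0
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = pos[order]
    tps = np.cumsum(p)
    fps = np.cumsum(~p)
    # keep only the last point of each tied-score run
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    return fpr, tpr


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal integration."""
    fpr, tpr = roc_curve_points(scores, labels)
    return float(np.trapezoid(tpr, fpr))


@dataclass
class ClassificationReport:
    """Cohort summary for one protocol."""

    task: str
    scheme: str
    subject_accuracies: dict[str, float]
    mean_accuracy: float
    sd_accuracy: float
    confusion: pd.DataFrame
    per_class_f1: dict[str, float]
    auc: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "scheme": self.scheme,
            "subject_accuracies": self.subject_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "confusion": {
                "classes": list(self.confusion.columns),
                "predicted_x_true": self.confusion.to_numpy().tolist(),
            },
            "per_class_f1": self.per_class_f1,
            "auc": self.auc,
            **self.extras,
        }


def summarize(task: str, scheme: str, results: list[SubjectResult]) -> ClassificationReport:
    """Pool per-subject results: mean (SD) accuracy across subjects, pooled
    confusion matrix and F1, and AUC from pooled decision scores."""
    if not results:
        raise ProtocolError("no subject results to summarize")
    accs = {r.subject: r.accuracy for r in results}
    conf = results[0].confusion.copy()
    for r in results[1:]:
        conf = conf.add(r.confusion, fill_value=0).astype(int)
    metrics = metrics_from_confusion(conf)
    auc = None
    if all(r.scores is not None for r in results):
        scores = np.concatenate([r.scores for r in results])
        labels = np.concatenate([r.score_labels for r in results])
        auc = roc_auc(scores, labels)
    vals = np.array(list(accs.values()))
    return ClassificationReport(
        task=task,
        scheme=scheme,
        subject_accuracies=accs,
        mean_accuracy=float(vals.mean()),
        sd_accuracy=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        confusion=conf,
        per_class_f1={c: m["f1"] for c, m in metrics["per_class"].items()},
        auc=auc,
    )
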