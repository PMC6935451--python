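"""Classification harness, quality indicators and segmentation agreement.

Positive class convention: following the clinical screening setup, the
*normal* class is the positive one (P = number of normal breasts), and the
abnormal class is negative.  All indicators derive from one confusion
matrix:

    TPR = TP/P          PPV = TP/(TP+FP)      FDR = FP/(FP+TP)
    F1  = 2TP/(2TP+FP+FN)                     HM  = 2 TPR PPV/(TPR+PPV)
    SPC = TN/N          NPV = TN/(TN+FN)      ACC = (TP+TN)/(P+N)
    FPR = FP/N

AUC is the Mann-Whitney rank statistic over positive-class scores (midranks
for ties).  Segmentation agreement uses the Zijdenbos Similarity Index
ZSI = 2|A1 n A2| / (|A1| + |A2|), identical to the Dice coefficient;
values above 0.75 are conventionally read as excellent agreement.

Four classifier kinds are supported behind one interface: a small seeded
NumPy CNN consuming segmented RGB images, and random-forest, multilayer-
perceptron and naive-Bayes learners consuming feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .cnn import SmallCNN
from .errors import (
    DegenerateTrainingError,
    ParameterError,
    StratificationError,
)

POSITIVE_LABEL = "normal"

CLASSIFIER_KINDS = ("cnn", "forest", "mlp", "bayes")


@dataclass
class ClassifierSpec:
    """Which learner to run and how.

    ``kind`` is one of ``cnn | forest | mlp | bayes``.  ``hyperparameters``
    are passed through to the underlying model.  ``input_side`` applies to
    the CNN only (the published pipeline feeds 277 x 277 x 3 segmented
    images; 227 or any smaller side is selectable).
    """

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    input_side: int = 277
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ParameterError(
                f"unknown classifier kind {self.kind!r}; expected one of "
                f"{CLASSIFIER_KINDS}")


@dataclass
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ParameterError("confusion-matrix counts must be >= 0")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.FP + self.TN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


@dataclass
class MetricsReport:
    """Confusion-derived quality indicators; undefined rates are NaN."""

    TPR: float
    PPV: float
    FDR: float
    F1: float
    HM: float
    SPC: float
    NPV: float
    ACC: float
    FPR: float
    AUC: float | None = None

    def as_dict(self) -> dict:
        return {
            "TPR": self.TPR, "PPV": self.PPV, "FDR": self.FDR, "F1": self.F1,
            "HM": self.HM, "SPC": self.SPC, "NPV": self.NPV, "ACC": self.ACC,
            "FPR": self.FPR, "AUC": self.AUC,
        }


@dataclass
class Predictions:
    labels: np.ndarray
    scores: np.ndarray  # positive-class score per test sample


@dataclass
class CVResult:
    fold_of: np.ndarray
    fold_matrices: list
    pooled: ConfusionMatrix
    report: MetricsReport
    seed: int


def segmented_cnn_input(image: np.ndarray, left_mask: np.ndarray,
                        right_mask: np.ndarray, side: int = 277) -> np.ndarray:
    """Build the CNN input: image masked to the segmented breasts, resized.

    Pixels outside both breast masks are zeroed, and the result is resized
    to ``side x side x 3`` (the published pipeline feeds 277; any smaller
    side works for reduced-scale experiments).
    """
    from skimage.transform import resize

    img = np.asarray(image, dtype=np.float64)
    keep = np.asarray(left_mask, bool) | np.asarray(right_mask, bool)
    masked = img * keep[..., None]
    return resize(masked, (side, side, 3), order=1, mode="constant",
                  anti_aliasing=True)


def confusion_from_labels(y_true, y_pred,
                          positive=POSITIVE_LABEL) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    return ConfusionMatrix(TP=tp, FP=fp, TN=tn, FN=fn)


def split_two_fold(labels, seed: int = 0) -> np.ndarray:
    """Stratified 2-fold assignment: array of fold ids (0 or 1) per sample.

    Both folds have near-equal size with per-class counts differing by at
    most one; the assignment is deterministic for a fixed seed.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise StratificationError(
            "each class needs at least 2 samples for a stratified 2-fold split")
    skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_of[test_idx] = fold
    return fold_of


def _build_model(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.kind == "forest":
        hp.setdefault("n_estimators", 200)
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.kind == "mlp":
        hp.setdefault("hidden_layer_sizes", (32,))
        hp.setdefault("max_iter", 2000)
        # features span orders of magnitude (areas vs entropies):
        # standardize before the perceptron
        return make_pipeline(StandardScaler(),
                             MLPClassifier(random_state=spec.seed, **hp))
    if spec.kind == "bayes":
        return GaussianNB(**hp)
    hp.setdefault("input_side", spec.input_side)
    hp.setdefault("seed", spec.seed)
    return SmallCNN(**hp)


def train_predict(spec: ClassifierSpec, X_train, y_train, X_test,
                  positive=POSITIVE_LABEL) -> Predictions:
    """Fit the requested learner and predict labels for the test set.

    ``X_*`` are feature matrices for the tabular kinds and image stacks
    ``(N, side, side, 3)`` for ``kind="cnn"``.  Returns per-sample labels
    and positive-class scores.
    """
    y_train = np.asarray(y_train)
    if len(y_train) == 0:
        raise DegenerateTrainingError("empty training set")
    if len(np.unique(y_train)) < 2:
        raise DegenerateTrainingError("training set has a single class")
    X_train = np.asarray(X_train, dtype=np.float64)
    X_test = np.asarray(X_test, dtype=np.float64)
    model = _build_model(spec)
    model.fit(X_train, y_train)
    if len(X_test) == 0:
        return Predictions(labels=np.asarray([], dtype=y_train.dtype),
                           scores=np.asarray([]))
    labels = model.predict(X_test)
    probs = model.predict_proba(X_test)
    pos_col = int(np.nonzero(model.classes_ == positive)[0][0])
    return Predictions(labels=np.asarray(labels), scores=probs[:, pos_col])


def cross_validate_two_fold(spec: ClassifierSpec, X, y, seed: int = 0,
                            positive=POSITIVE_LABEL) -> CVResult:
    """Both directions of a stratified 2-fold split, pooled."""
    y = np.asarray(y)
    fold_of = split_two_fold(y, seed=seed)
    X = np.asarray(X, dtype=np.float64)
    fold_cms = []
    scores = np.empty(len(y), dtype=float)
    preds = np.empty(len(y), dtype=y.dtype)
    for test_fold in (0, 1):
        test = fold_of == test_fold
        train = ~test
        pred = train_predict(spec, X[train], y[train], X[test], positive=positive)
        preds[test] = pred.labels
        scores[test] = pred.scores
        fold_cms.append(confusion_from_labels(y[test], pred.labels, positive))
    pooled = fold_cms[0] + fold_cms[1]
    report = metrics(pooled, scores=scores, y_true=y, positive=positive)
    return CVResult(fold_of=fold_of, fold_matrices=fold_cms, pooled=pooled,
                    report=report, seed=seed)


def _rate(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cm: ConfusionMatrix, scores=None, y_true=None,
            positive=POSITIVE_LABEL) -> MetricsReport:
    """All quality indicators of a confusion matrix (plus AUC from scores).

    Zero-denominator indicators are reported as NaN, never silently 0.
    AUC is omitted (None) when scores are absent.
    """
    tp, fp, tn, fn = cm.TP, cm.FP, cm.TN, cm.FN
    tpr = _rate(tp, cm.P)
    ppv = _rate(tp, tp + fp)
    fdr = _rate(fp, fp + tp)
    f1 = _rate(2 * tp, 2 * tp + fp + fn)
    hm = (2 * tpr * ppv / (tpr + ppv)
          if np.isfinite(tpr) and np.isfinite(ppv) and (tpr + ppv) > 0
          else float("nan"))
    spc = _rate(tn, cm.N)
    npv = _rate(tn, tn + fn)
    acc = _rate(tp + tn, tp + fp + tn + fn)
    fpr = _rate(fp, cm.N)
    auc = None
    if scores is not None:
        if y_true is None:
            raise ParameterError("AUC needs y_true alongside scores")
        y_true = np.asarray(y_true)
        y_bin = (y_true == positive).astype(int)
        if 0 < y_bin.sum() < len(y_bin):
            auc = float(roc_auc_score(y_bin, np.asarray(scores, dtype=float)))
    return MetricsReport(TPR=tpr, PPV=ppv, FDR=fdr, F1=f1, HM=hm, SPC=spc,
                         NPV=npv, ACC=acc, FPR=fpr, AUC=auc)


def zsi(a1: np.ndarray, a2: np.ndarray) -> float:
    """Zijdenbos Similarity Index of two binary masks (== Dice overlap)."""
    a1 = np.asarray(a1, dtype=bool)
    a2 = np.asarray(a2, dtype=bool)
    if a1.shape != a2.shape:
        raise ParameterError(
            f"mask shapes differ: {a1.shape} vs {a2.shape}")
    total = int(a1.sum()) + int(a2.sum())
    if total == 0:
        raise ParameterError("ZSI of two empty masks is undefined")
    return 2.0 * int((a1 & a2).sum()) / total
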