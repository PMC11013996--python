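"""Exercise recognition: features, PCA, classifiers, evaluation.

Each exercise repetition is described by 19 features (12 time-domain,
7 frequency-domain) of 15 motion signals — the x, y, z traces of five
basic body keypoints (torso, both arms, both legs) — giving a 285-dim
feature vector.  The feature space can be reduced by PCA to the
smallest leading set of components explaining 90 % of the variance.
Five classifiers (random forest, linear / polynomial / RBF SVM,
decision tree) are trained and compared on a subject-wise split: the
test set contains only unseen subjects, so performance reflects
generalization to new people, not re-identification.

scikit-learn provides the estimators; this module owns the feature
definitions, the subject-wise protocol and the reporting.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from enum import IntEnum
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from . import landmarks as lm
from .pose_model import SignalSet
from .signal_prep import MotionSignal

__all__ = [
    "ExerciseLabel",
    "BasicKeypointSet",
    "FeatureVector",
    "PCAModel",
    "DatasetSplit",
    "ClassifierReport",
    "ExerciseModel",
    "TIME_FEATURES",
    "FREQ_FEATURES",
    "FEATURE_NAMES",
    "N_FEATURES",
    "select_basic_signals",
    "extract_features",
    "fit_pca",
    "split_by_subject",
    "train_and_evaluate",
    "fit_model",
    "predict_exercise",
    "save_model",
    "load_model",
]


class ExerciseLabel(IntEnum):
    """The five-exercise repertoire, class-coded 1..5."""

    SS = 1   # side steps
    SA = 2   # shoulder abductions
    TR = 3   # trunk rotation
    FB = 4   # standing forward bends
    SQT = 5  # squats


@dataclass(frozen=True)
class BasicKeypointSet:
    """The five basic body keypoints feeding the feature extractor.

    Distal points carry the most motion signal, so the defaults are the
    wrists and ankles; the torso is the virtual mid-hip point (mean of
    the two hip landmarks).
    """

    torso: Union[int, str] = "midhip"
    left_arm: int = lm.LEFT_WRIST
    right_arm: int = lm.RIGHT_WRIST
    left_leg: int = lm.LEFT_ANKLE
    right_leg: int = lm.RIGHT_ANKLE

    @property
    def roles(self) -> Tuple[Tuple[str, Union[int, str]], ...]:
        return (
            ("torso", self.torso),
            ("left_arm", self.left_arm),
            ("right_arm", self.right_arm),
            ("left_leg", self.left_leg),
            ("right_leg", self.right_leg),
        )


TIME_FEATURES = (
    "mean", "max", "min", "rms", "variance", "std", "crest_factor",
    "kurtosis", "skewness", "median", "peak_to_peak", "energy",
)
FREQ_FEATURES = (
    "bp_mean", "bp_max", "bp_sum", "bp_std", "bp_peak_freq",
    "bp_kurtosis", "bp_skewness",
)
_ROLES = ("torso", "left_arm", "right_arm", "left_leg", "right_leg")
FEATURE_NAMES: Tuple[str, ...] = tuple(
    f"{role}_{axis}_{feat}"
    for role in _ROLES
    for axis in lm.AXES
    for feat in TIME_FEATURES + FREQ_FEATURES
)
N_FEATURES = len(FEATURE_NAMES)  # 19 features x 15 signals = 285


@dataclass
class FeatureVector:
    """One repetition's 285-dim descriptor."""

    values: np.ndarray
    names: Tuple[str, ...] = FEATURE_NAMES
    label: Optional[ExerciseLabel] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have {N_FEATURES} values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")
        if len(self.names) != N_FEATURES or len(set(self.names)) != N_FEATURES:
            raise ValueError("feature names must be unique and complete")


def select_basic_signals(
    ss: SignalSet,
    bset: Optional[BasicKeypointSet] = None,
) -> List[MotionSignal]:
    """The 15 basic-keypoint signals, ordered (role, axis)."""
    bset = bset or BasicKeypointSet()
    out: List[MotionSignal] = []
    for role, kp in bset.roles:
        for axis in lm.AXES:
            if kp == "midhip":
                vals = (ss.get(lm.LEFT_HIP, axis).values
                        + ss.get(lm.RIGHT_HIP, axis).values) / 2.0
            else:
                vals = ss.get(int(kp), axis).values
            out.append(MotionSignal(vals, ss.fs, (role, axis)))
    return out


def _time_features(x: np.ndarray) -> List[float]:
    rms = float(np.sqrt(np.mean(x**2)))
    var = float(np.var(x))
    if var < 1e-24:
        # conventions for a constant signal: unit crest factor, no shape
        crest, kurt, skew = 1.0, 0.0, 0.0
    else:
        crest = float(np.max(np.abs(x)) / rms) if rms > 0 else 1.0
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
        skew = float(stats.skew(x, bias=True))
    return [
        float(np.mean(x)), float(np.max(x)), float(np.min(x)), rms, var,
        float(np.std(x)), crest, kurt, skew, float(np.median(x)),
        float(np.max(x) - np.min(x)), float(np.sum(x**2)),
    ]


def _freq_features(x: np.ndarray, fs: float) -> List[float]:
    # Hann-windowed periodogram of the mean-removed segment over [0, fs/2].
    f, pxx = sps.periodogram(x, fs=fs, window="hann", detrend="constant")
    if np.allclose(pxx, 0.0):
        return [0.0] * len(FREQ_FEATURES)
    peak = float(f[int(np.argmax(pxx))])
    if np.var(pxx) < 1e-30:
        k, s = 0.0, 0.0
    else:
        k = float(stats.kurtosis(pxx, fisher=False, bias=True))
        s = float(stats.skew(pxx, bias=True))
    return [float(np.mean(pxx)), float(np.max(pxx)), float(np.sum(pxx)),
            float(np.std(pxx)), peak, k, s]


def extract_features(
    signals: Sequence[MotionSignal],
    fs: Optional[float] = None,
    label: Optional[ExerciseLabel] = None,
    subject_id: str = "",
) -> FeatureVector:
    """The 285-dim feature vector of one repetition.

    ``signals`` must be the 15 basic-keypoint traces of a single
    repetition segment, each at least 8 samples long.
    """
    if len(signals) != 15:
        raise ValueError(f"expected 15 basic signals, got {len(signals)}")
    vals: List[float] = []
    for sig in signals:
        x = np.asarray(sig.values, dtype=float)
        if x.size < 8:
            raise ValueError("each signal needs at least 8 samples (one repetition)")
        if not np.all(np.isfinite(x)):
            raise ValueError("signals must be finite")
        vals.extend(_time_features(x))
        vals.extend(_freq_features(x, fs or sig.fs))
    return FeatureVector(np.array(vals), FEATURE_NAMES, label, subject_id)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Standardize-then-PCA transform retaining >= target variance."""

    scaler: object
    pca: object
    n_retained: int
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(self.scaler.transform(X))

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return self.scaler.inverse_transform(self.pca.inverse_transform(Z))

    @property
    def components(self) -> np.ndarray:
        return self.pca.components_

    @property
    def mean(self) -> np.ndarray:
        return self.scaler.mean_


def fit_pca(X: np.ndarray, target_var: float = 0.90) -> PCAModel:
    """Fit a z-score + PCA reduction keeping >= ``target_var`` variance.

    Features are standardized first — they mix heterogeneous scales
    (normalized positions, spectral powers, dimensionless shape
    statistics).  Retains the smallest leading component set whose
    cumulative explained variance reaches the target.
    """
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if not np.any(np.var(X, axis=0) > 0):
        raise ValueError("degenerate data: no feature has variance")
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    pca = PCA(n_components=target_var, svd_solver="full").fit(Z)
    return PCAModel(scaler, pca, int(pca.n_components_),
                    np.asarray(pca.explained_variance_ratio_))


# ---------------------------------------------------------------------------
# Splitting / training / evaluation


@dataclass
class DatasetSplit:
    train_subjects: List[str]
    test_subjects: List[str]
    test_fraction_target: float
    test_fraction_actual: float

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.test_subjects):
            raise ValueError("a subject cannot appear in both train and test")
        if not self.train_subjects or not self.test_subjects:
            raise ValueError("both splits must be non-empty")


def split_by_subject(
    table: pd.DataFrame,
    test_fraction: float = 0.30,
    seed: int = 0,
) -> DatasetSplit:
    """Subject-wise train/test split.

    Subjects are shuffled (seeded) and moved into the test set while
    doing so brings the test repetition count closer to
    ``test_fraction`` of all records; no subject ever straddles the
    split, so no identity information leaks into evaluation.
    """
    subjects = list(pd.unique(table["subject_id"]))
    if len(subjects) < 2:
        raise ValueError("subject-wise split needs at least two subjects")
    counts = table["subject_id"].value_counts()
    total = int(counts.sum())
    target = test_fraction * total
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    test: List[str] = []
    acc = 0
    for s in order[:-1]:  # always keep at least one training subject
        c = int(counts[s])
        if abs(acc + c - target) <= abs(acc - target):
            test.append(s)
            acc += c
        else:
            break
    if not test:
        test, acc = [order[0]], int(counts[order[0]])
    train = [s for s in order if s not in test]
    return DatasetSplit(train, test, test_fraction, acc / total)


CLASSIFIER_KEYS = ("RF", "SVML", "SVMP", "SVMRBF", "DT")


def _make_classifiers(seed: int) -> Dict[str, object]:
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "RF": RandomForestClassifier(n_estimators=100, random_state=seed),
        "SVML": SVC(kernel="linear", C=1.0),
        "SVMP": SVC(kernel="poly", degree=3, C=1.0),
        "SVMRBF": SVC(kernel="rbf", gamma="scale", C=1.0),
        "DT": DecisionTreeClassifier(random_state=seed),
    }


@dataclass
class ClassifierReport:
    """Test-set metrics (percent) per classifier, plus CV and timings."""

    metrics: Dict[str, Dict[str, float]]
    per_class_accuracy: Dict[str, Dict[int, float]]
    confusion: Dict[str, np.ndarray]
    cv_accuracy: Dict[str, float]
    classes: List[int]
    n_train: int
    n_test: int
    use_pca: bool
    n_components: Optional[int] = None

    def best(self, metric: str = "accuracy") -> str:
        return max(self.metrics, key=lambda k: self.metrics[k][metric])

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "use_pca": self.use_pca,
            "n_components": self.n_components,
            "cv_accuracy": self.cv_accuracy,
            "metrics": self.metrics,
            "per_class_accuracy": {
                k: {str(c): v for c, v in d.items()}
                for k, d in self.per_class_accuracy.items()
            },
            "confusion": {k: v.tolist() for k, v in self.confusion.items()},
        }


def _macro_specificity(cm: np.ndarray) -> float:
    total = cm.sum()
    specs = []
    for i in range(cm.shape[0]):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        tn = total - tp - fp - fn
        specs.append(tn / (tn + fp) if (tn + fp) > 0 else 0.0)
    return float(np.mean(specs))


def _split_matrices(table: pd.DataFrame, split: DatasetSplit):
    feat_cols = [c for c in table.columns if c not in ("subject_id", "label")]
    tr = table[table["subject_id"].isin(split.train_subjects)]
    te = table[table["subject_id"].isin(split.test_subjects)]
    # leakage guard in the evaluation path itself, not just the splitter
    overlap = set(tr["subject_id"]) & set(te["subject_id"])
    if overlap:
        raise ValueError(f"subject leakage between train and test: {overlap}")
    return (tr[feat_cols].to_numpy(float), tr["label"].to_numpy(int),
            te[feat_cols].to_numpy(float), te["label"].to_numpy(int))


def train_and_evaluate(
    table: pd.DataFrame,
    split: DatasetSplit,
    use_pca: bool = True,
    cv_folds: int = 10,
    seed: int = 0,
    target_var: float = 0.90,
) -> ClassifierReport:
    """Train all five classifiers and report held-out test metrics.

    The scaler and PCA are fit on the training subjects only.  Reports
    stratified ``cv_folds``-fold cross-validation accuracy on the
    training set plus, on the unseen-subject test set: accuracy, macro
    F1 / precision / sensitivity / specificity (percent), per-class
    accuracy, the confusion matrix, and training / inference wall time.
    """
    from sklearn.metrics import (confusion_matrix, f1_score, precision_score,
                                 recall_score)
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.preprocessing import StandardScaler

    Xtr, ytr, Xte, yte = _split_matrices(table, split)
    classes = sorted(np.unique(ytr).tolist())
    if sorted(np.unique(np.concatenate([ytr, yte])).tolist()) != classes:
        raise ValueError("every class must be present in the training set")

    n_comp = None
    if use_pca:
        model = fit_pca(Xtr, target_var)
        Ztr, Zte = model.transform(Xtr), model.transform(Xte)
        n_comp = model.n_retained
    else:
        scaler = StandardScaler().fit(Xtr)
        Ztr, Zte = scaler.transform(Xtr), scaler.transform(Xte)

    metrics: Dict[str, Dict[str, float]] = {}
    per_class: Dict[str, Dict[int, float]] = {}
    confusion: Dict[str, np.ndarray] = {}
    cv_acc: Dict[str, float] = {}
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for key, clf in _make_classifiers(seed).items():
        cv_acc[key] = float(np.mean(
            cross_val_score(clf, Ztr, ytr, cv=skf, scoring="accuracy")))
        t0 = time.perf_counter()
        clf.fit(Ztr, ytr)
        tt = time.perf_counter() - t0
        t0 = time.perf_counter()
        pred = clf.predict(Zte)
        it = time.perf_counter() - t0
        cm = confusion_matrix(yte, pred, labels=classes)
        metrics[key] = {
            "accuracy": 100.0 * float(np.mean(pred == yte)),
            "f1": 100.0 * float(f1_score(yte, pred, average="macro")),
            "precision": 100.0 * float(precision_score(
                yte, pred, average="macro", zero_division=0)),
            "sensitivity": 100.0 * float(recall_score(
                yte, pred, average="macro", zero_division=0)),
            "specificity": 100.0 * _macro_specificity(cm),
            "training_time_s": tt,
            "inference_time_s": it,
        }
        with np.errstate(invalid="ignore", divide="ignore"):
            row = cm.sum(axis=1)
            pc = np.where(row > 0, np.diag(cm) / np.maximum(row, 1), 0.0)
        per_class[key] = {c: 100.0 * float(pc[i]) for i, c in enumerate(classes)}
        confusion[key] = cm
    return ClassifierReport(metrics, per_class, confusion, cv_acc, classes,
                            len(ytr), len(yte), use_pca, n_comp)


# ---------------------------------------------------------------------------
# Deployable model bundle


@dataclass
class ExerciseModel:
    """A fitted scaler (+ optional PCA) + classifier + feature spec."""

    scaler: object
    pca: Optional[object]
    clf: object
    feature_names: Tuple[str, ...] = FEATURE_NAMES
    classifier_key: str = "SVML"
    version: str = "1"

    def _project(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(X)
        return self.pca.transform(Z) if self.pca is not None else Z


def fit_model(
    table: pd.DataFrame,
    classifier: str = "SVML",
    use_pca: bool = True,
    seed: int = 0,
    target_var: float = 0.90,
) -> ExerciseModel:
    """Fit one deployable classifier on a full feature table."""
    from sklearn.preprocessing import StandardScaler

    feat_cols = [c for c in table.columns if c not in ("subject_id", "label")]
    X = table[feat_cols].to_numpy(float)
    y = table["label"].to_numpy(int)
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    pca = None
    if use_pca:
        from sklearn.decomposition import PCA

        pca = PCA(n_components=target_var, svd_solver="full").fit(Z)
        Z = pca.transform(Z)
    clf = _make_classifiers(seed)[classifier]
    clf.fit(Z, y)
    return ExerciseModel(scaler, pca, clf, tuple(feat_cols), classifier)


def predict_exercise(model: ExerciseModel, fv: FeatureVector) -> Tuple[ExerciseLabel, float]:
    """Predict the exercise of one repetition, with a confidence score.

    The score is the top class-membership probability when the
    classifier provides one, else its top one-vs-rest decision value.
    Deterministic given a fitted model.
    """
    if tuple(fv.names) != tuple(model.feature_names):
        raise ValueError("feature specification mismatch with the model")
    X = fv.values.reshape(1, -1)
    Z = model._project(X)
    pred = int(model.clf.predict(Z)[0])
    if hasattr(model.clf, "predict_proba"):
        score = float(np.max(model.clf.predict_proba(Z)))
    elif hasattr(model.clf, "decision_function"):
        d = np.atleast_2d(model.clf.decision_function(Z))
        score = float(np.max(d))
    else:  # pragma: no cover
        score = float("nan")
    return ExerciseLabel(pred), score


def save_model(model: ExerciseModel, path) -> None:
    import joblib

    joblib.dump({
        "version": model.version,
        "classifier_key": model.classifier_key,
        "feature_names": list(model.feature_names),
        "scaler": model.scaler,
        "pca": model.pca,
        "clf": model.clf,
    }, path)


def load_model(path, expected_features: Sequence[str] = FEATURE_NAMES) -> ExerciseModel:
    import joblib

    blob = joblib.load(path)
    if list(blob["feature_names"]) != list(expected_features):
        raise ValueError("model bundle feature specification mismatch")
    return ExerciseModel(blob["scaler"], blob["pca"], blob["clf"],
                         tuple(blob["feature_names"]), blob["classifier_key"],
                         blob["version"])
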