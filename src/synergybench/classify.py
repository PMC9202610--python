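"""Task-space evaluation: synergy features + standard classifiers.

One synergy (k = 1) is extracted from every movement trial with a chosen
extraction method; the unit-normalized, sign-resolved synergy vector is the
trial's feature.  Features feed four standard classifiers — KNN (5
neighbours, Euclidean), LDA, linear-kernel SVM (one-vs-one multiclass) and a
random forest with 50 trees — under stratified 5-fold cross-validation with
shared fold assignments, so classifier comparisons see identical splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .factorizers import METHODS
from .synthgen import MovementDataset

__all__ = [
    "FeatureVector",
    "CVResult",
    "CLASSIFIERS",
    "extract_trial_feature",
    "extract_features",
    "make_classifier",
    "run_cv",
    "accuracy_table",
    "load_movement_trials",
]

CLASSIFIERS = ("KNN", "LDA", "SVM", "RF")


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    label: int
    method: str
    trial_id: int = -1
    repetition: int = -1


@dataclass(frozen=True)
class CVResult:
    method: str
    classifier: str
    fold_accuracies: np.ndarray
    mean_accuracy: float
    seed: int


def _resolve_sign(w: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry positive (removes the sign ambiguity
    of PCA/ICA/FA components as a classification nuisance)."""
    return w * np.sign(w[np.argmax(np.abs(w))]) if w[np.argmax(np.abs(w))] != 0 else w


def extract_trial_feature(M: np.ndarray, method: str, seed: int = 0,
                          **method_kwargs) -> np.ndarray:
    """Single-synergy (k = 1) feature of one trial envelope matrix (m x T).

    Returns the unit-normalized, sign-resolved synergy vector of length m.
    """
    cls = METHODS[method.upper()]
    kwargs = dict(method_kwargs)
    if method.upper() in ("ICA", "NMF", "AE"):
        kwargs.setdefault("random_state", seed)
    est = cls(n_components=1, **kwargs)
    est.fit(np.asarray(M, dtype=float).T)
    w = est.components_[0].copy()
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("degenerate trial: zero synergy vector")
    return _resolve_sign(w / nrm)


def extract_features(dataset: MovementDataset, method: str, seed: int = 0,
                     **method_kwargs) -> tuple[np.ndarray, np.ndarray]:
    """Features and labels for a whole movement dataset; (N, m) and (N,)."""
    feats, labels = [], []
    for i, (M, label, _rep) in enumerate(dataset.trials):
        feats.append(extract_trial_feature(M, method, seed=seed + i, **method_kwargs))
        labels.append(label)
    return np.asarray(feats), np.asarray(labels)


def load_movement_trials(directory, mat_adapter: bool = False) -> MovementDataset:
    """Load user-supplied movement trials from delimited-text files.

    Expects ``labels.csv`` with columns ``trial_id,label,repetition`` and one
    ``trial<id>.csv`` (muscles x samples) per row.  ``mat_adapter=True``
    additionally accepts ``trial<id>.mat`` files holding an ``emg`` array
    (the layout used by public multichannel sEMG repositories); this path is
    a convenience adapter and is not exercised by the benchmark.
    """
    import csv
    from pathlib import Path

    directory = Path(directory)
    trials = []
    with open(directory / "labels.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            tid, label, rep = int(row["trial_id"]), int(row["label"]), int(row["repetition"])
            csv_path = directory / f"trial{tid}.csv"
            if csv_path.exists():
                M = np.atleast_2d(np.loadtxt(csv_path, delimiter=","))
            elif mat_adapter and (directory / f"trial{tid}.mat").exists():
                from scipy.io import loadmat

                M = np.atleast_2d(np.asarray(loadmat(directory / f"trial{tid}.mat")["emg"],
                                             dtype=float))
            else:
                raise FileNotFoundError(f"no matrix file for trial {tid}")
            if M.min() < 0:
                raise ValueError(f"trial {tid}: envelope matrices must be non-negative")
            trials.append((M, label, rep))
    if not trials:
        raise ValueError("labels.csv lists no trials")
    templates = np.zeros((len(set(lab for _, lab, _ in trials)), trials[0][0].shape[0]))
    return MovementDataset(trials=trials, class_templates=templates, noise_sd=float("nan"))


def make_classifier(tag: str, seed: int = 0):
    tag = tag.upper()
    if tag == "KNN":
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    if tag == "LDA":
        return LinearDiscriminantAnalysis()
    if tag == "SVM":
        # SVC trains one-vs-one binary problems for multiclass input
        return SVC(kernel="linear", random_state=seed)
    if tag == "RF":
        return RandomForestClassifier(n_estimators=50, random_state=seed)
    raise ValueError(f"unknown classifier {tag!r}; expected one of {CLASSIFIERS}")


def cv_splits(labels: np.ndarray, seed: int, n_splits: int = 5):
    """Stratified fold assignment — a function of (labels, seed) only, so all
    methods and classifiers share identical splits."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if np.any(counts < n_splits):
        raise ValueError(
            f"every class needs at least {n_splits} samples for {n_splits}-fold CV"
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def run_cv(features: np.ndarray, labels: np.ndarray, classifier: str,
           seed: int = 0, method: str = "") -> CVResult:
    """Stratified 5-fold CV; accuracy is the fraction correct pooled over folds."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    folds = cv_splits(y, seed)
    fold_acc = []
    n_correct = 0
    for train, test in folds:
        clf = make_classifier(classifier, seed)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        fold_acc.append(float(np.mean(pred == y[test])))
        n_correct += int(np.sum(pred == y[test]))
    return CVResult(
        method=method, classifier=classifier.upper(),
        fold_accuracies=np.asarray(fold_acc),
        mean_accuracy=n_correct / len(y), seed=seed,
    )


def accuracy_table(results: list[CVResult],
                   expected_methods: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Tidy method x classifier accuracy table with per-method rankings.

    When ``expected_methods`` is given, any missing (method, classifier) cell
    raises, flagging an incomplete result set.
    """
    rows = [
        {
            "method": r.method,
            "classifier": r.classifier,
            "mean_accuracy": r.mean_accuracy,
            "sd_accuracy": float(np.std(r.fold_accuracies, ddof=1)),
            "seed": r.seed,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if expected_methods is not None:
        want = {(m, c) for m in expected_methods for c in CLASSIFIERS}
        have = set(zip(df["method"], df["classifier"]))
        missing = want - have
        if missing:
            raise ValueError(f"incomplete result set; missing cells: {sorted(missing)}")
    df["rank_within_method"] = df.groupby("method")["mean_accuracy"].rank(
        ascending=False, method="min"
    )
    return df.sort_values(["method", "classifier"]).reset_index(drop=True)
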