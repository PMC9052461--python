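"""Three-criterion evaluation of a selected feature subset.

* classification accuracy under repeated stratified k-fold CV with four
  classifiers (C4.5-style entropy tree, Gaussian Naive Bayes, KNN with
  the sqrt(n_train) rule, AdaBoost on depth-1 stumps);
* redundancy rate — mean pairwise similarity over the subset, under
  normalized mutual information (discretized data) or |Pearson r|
  (continuous data);
* representation entropy — Shannon entropy (bits) of the normalized
  eigen-spectrum of the subset's covariance matrix.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .data_model import ClassLabels, DiscretizedMatrix, OmicsMatrix
from .infotheory import normalized_mi

__all__ = [
    "CLASSIFIERS",
    "ConfusionCounts",
    "AccuracyEstimate",
    "SpectrumSummary",
    "confusion_counts",
    "cv_accuracy",
    "redundancy_rate",
    "representation_entropy",
    "DEFAULT_GRIDS",
]

CLASSIFIERS = ("C45", "NaiveBayes", "KNN", "AdaBoost")

#: hyperparameter grids of the benchmark protocol: KNN neighbors 1..15,
#: tree confidence 0.05..0.5 step 0.05; NB and AdaBoost have none.
DEFAULT_GRIDS = {
    "KNN": [{"n_neighbors": k} for k in range(1, 16)],
    "C45": [{"confidence": round(c, 2)} for c in np.arange(0.05, 0.501, 0.05)],
}


@dataclass(frozen=True)
class ConfusionCounts:
    """Multiclass confusion matrix plus per-class one-vs-rest reductions."""

    classes: tuple[str, ...]
    matrix: np.ndarray
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    @property
    def accuracy(self) -> float:
        """Fraction of correct predictions (multiclass reading of
        (TP+TN)/(TP+TN+FP+FN), which it equals exactly for 2 classes)."""
        return float(np.trace(self.matrix) / self.matrix.sum())


def confusion_counts(y_true, y_pred, classes: tuple[str, ...] | None = None
                     ) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = list(classes) if classes else sorted(set(y_true) | set(y_pred))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    tp = np.diag(cm).astype(int)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = cm.sum() - tp - fp - fn
    return ConfusionCounts(tuple(str(c) for c in labels), cm, tp, tn, fp, fn)


@dataclass(frozen=True)
class AccuracyEstimate:
    classifier: str
    mean_pct: float
    std_pct: float
    folds: int
    repeats: int
    seed: int
    best_params: dict = field(default_factory=dict)


def _make_classifier(name: str, n_train: int, seed: int, hyper: dict):
    if name == "C45":
        confidence = hyper.get("confidence")
        # Weka-style confidence: smaller = heavier pruning; mapped
        # monotonically onto cost-complexity pruning strength.
        ccp = 0.0 if confidence is None else 0.05 * (0.5 - confidence)
        return DecisionTreeClassifier(criterion="entropy", ccp_alpha=max(ccp, 0.0),
                                      random_state=seed)
    if name == "NaiveBayes":
        return GaussianNB()
    if name == "KNN":
        k = hyper.get("n_neighbors") or max(1, round(math.sqrt(n_train)))
        return KNeighborsClassifier(n_neighbors=min(k, n_train))
    if name == "AdaBoost":
        stump = DecisionTreeClassifier(max_depth=1)
        return AdaBoostClassifier(estimator=stump, n_estimators=50,
                                  random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def _fold_accuracies(X: np.ndarray, y: np.ndarray, name: str, hyper: dict,
                     folds: int, repeats: int, seed: int) -> np.ndarray:
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=seed)
    accs = []
    for train, test in cv.split(X, y):
        clf = _make_classifier(name, len(train), seed, hyper)
        clf.fit(X[train], y[train])
        accs.append(float((clf.predict(X[test]) == y[test]).mean()))
    return np.array(accs) * 100.0


def cv_accuracy(data: OmicsMatrix, labels: ClassLabels,
                features, classifier: str,
                folds: int = 10, repeats: int = 10, seed: int = 0,
                tuning: list[dict] | None = None) -> AccuracyEstimate:
    """Repeated stratified k-fold accuracy (percent) of one classifier on
    one feature subset.

    With a ``tuning`` grid each setting gets a full repeated-CV run and
    the best mean is reported (the benchmark's tuned protocol); without
    one, the fixed rules apply — notably KNN's K = round(sqrt(n_train)).
    Stratification requires every class to hold at least ``folds``
    samples.  Same seed, same inputs -> identical estimate.
    """
    features = list(features)
    if not features:
        raise ValueError("feature subset must be non-empty")
    sub = data.subset_features(features)
    if list(sub.sample_ids) != list(labels.sample_ids):
        raise ValueError("data and labels must be aligned on samples")
    y = labels.codes()
    counts = np.bincount(y, minlength=labels.n_classes)
    if counts.min() < folds:
        raise ValueError(f"stratified {folds}-fold CV infeasible: smallest "
                         f"class has {counts.min()} samples")
    X = sub.values.T

    grid = tuning if tuning else [{}]
    best: tuple[float, float, dict] | None = None
    for hyper in grid:
        accs = _fold_accuracies(X, y, classifier, hyper, folds, repeats, seed)
        cand = (float(accs.mean()), float(accs.std(ddof=0)), hyper)
        if best is None or cand[0] > best[0]:
            best = cand
    return AccuracyEstimate(classifier=classifier, mean_pct=best[0],
                            std_pct=best[1], folds=folds, repeats=repeats,
                            seed=seed, best_params=dict(best[2]))


def redundancy_rate(data: OmicsMatrix | DiscretizedMatrix,
                    sim: str = "pearson") -> float:
    """Mean pairwise similarity over all feature pairs of the subset.

    RR = 2/(d(d-1)) * sum_{j>i} Sim(f_i, f_j), in [0, 1]; lower means a
    less redundant subset.  ``sim="nmi"`` expects discretized rows,
    ``sim="pearson"`` uses |r| on continuous rows (absolute value so
    anticorrelated pairs do not cancel).
    """
    d = len(data.feature_ids)
    if d < 2:
        raise ValueError("redundancy rate needs at least 2 features")
    if sim == "pearson":
        values = data.values if isinstance(data, OmicsMatrix) else \
            data.states.astype(float)
        r = np.corrcoef(values)
        iu = np.triu_indices(d, k=1)
        sims = np.abs(r[iu])
        sims = np.nan_to_num(sims, nan=0.0)  # constant rows: define r = 0
    elif sim == "nmi":
        rows = data.states if isinstance(data, DiscretizedMatrix) else data.values
        sims = np.array([normalized_mi(rows[i], rows[j])
                         for i, j in itertools.combinations(range(d), 2)])
    else:
        raise ValueError(f"unknown similarity {sim!r}; use 'nmi' or 'pearson'")
    return float(sims.mean())


@dataclass(frozen=True)
class SpectrumSummary:
    """Eigen-spectrum of the subset covariance and its entropy in bits."""

    eigenvalues: np.ndarray
    normalized: np.ndarray
    entropy_bits: float


def representation_entropy(data: OmicsMatrix, ddof: int = 1) -> SpectrumSummary:
    """Shannon entropy of the normalized covariance eigenvalues.

    RE = -sum lambda~_i log2 lambda~_i with lambda~ = lambda / sum(lambda).
    Zero when one eigenvalue carries all variance (all features collinear);
    maximal at log2 d when the eigenvalues are equal (information spread
    evenly over the subset).  Tiny negative eigenvalues from finite
    precision are clamped at 0.
    """
    d = len(data.feature_ids)
    if d < 2:
        raise ValueError("representation entropy needs at least 2 features")
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples")
    cov = np.cov(data.values, ddof=ddof)
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0.0, None)[::-1]
    total = lam.sum()
    if total == 0:
        raise ValueError("all-zero covariance: representation entropy undefined")
    tilde = lam / total
    nz = tilde[tilde > 0]
    ent = float(-(nz * np.log2(nz)).sum())
    return SpectrumSummary(eigenvalues=lam, normalized=tilde, entropy_bits=ent)
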