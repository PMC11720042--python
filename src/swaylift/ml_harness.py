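"""Cross-validated risk classification over sway-feature tables.

Evaluation machinery: stratified 10-fold cross-validation, optional greedy
backward feature elimination (BFE) wrapped around the classifier itself,
max-min normalisation for the scale-sensitive models, and a battery of
classifiers with fixed (pre-optimised) hyperparameters.  Test-fold
predictions are pooled into a single confusion matrix from which the seven
reporting metrics are derived; the area under the ROC curve is computed on
the pooled class scores.

Label convention: the two classes are "No-Risk" and "Risk", and *No-Risk is
the positive class* -- sensitivity is the fraction of No-Risk sessions
recognised as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .sway_features import FEATURE_NAMES

NO_RISK = "No-Risk"
RISK = "Risk"

METRIC_NAMES = [
    "accuracy",
    "f_measure",
    "specificity",
    "sensitivity",
    "precision",
    "recall",
    "aucroc",
]


class HarnessError(ValueError):
    pass


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    seed: int = 0
    stratified: bool = True  # kept for clarity; folds are always stratified


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    needs_scaling: bool = False


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts, actual x predicted, with No-Risk as the positive class."""

    n_nr_nr: int  # actual No-Risk, predicted No-Risk (TP)
    n_nr_r: int  # actual No-Risk, predicted Risk     (FN)
    n_r_nr: int  # actual Risk, predicted No-Risk     (FP)
    n_r_r: int  # actual Risk, predicted Risk         (TN)

    def __post_init__(self) -> None:
        if min(self.n_nr_nr, self.n_nr_r, self.n_r_nr, self.n_r_r) < 0:
            raise HarnessError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_nr_nr + self.n_nr_r + self.n_r_nr + self.n_r_r

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str]
    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            int(np.sum((y_true == NO_RISK) & (y_pred == NO_RISK))),
            int(np.sum((y_true == NO_RISK) & (y_pred == RISK))),
            int(np.sum((y_true == RISK) & (y_pred == NO_RISK))),
            int(np.sum((y_true == RISK) & (y_pred == RISK))),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.n_nr_nr, self.n_nr_r], [self.n_r_nr, self.n_r_r]],
            index=pd.Index([NO_RISK, RISK], name="actual"),
            columns=pd.Index([NO_RISK, RISK], name="predicted"),
        )


@dataclass
class EvaluationReport:
    classifier: str
    metrics: dict[str, float]
    confusion: ConfusionMatrix
    selected_features: list[str]
    per_fold: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Custom estimators


class PNNClassifier(BaseEstimator, ClassifierMixin):
    """Probabilistic neural network trained by dynamic decay adjustment.

    Gaussian radial units are committed per class during training: a sample
    already covered by a same-class unit (activation >= theta_plus) only
    reinforces that unit's weight; otherwise a new unit is committed at the
    sample.  Units of the opposite class whose activation at the sample
    exceeds theta_minus have their radii shrunk until it does not.  The
    class score is the weighted sum of unit activations.
    """

    def __init__(self, theta_minus: float = 0.113, theta_plus: float = 0.509,
                 max_epochs: int = 131, init_sigma: float = 10.0):
        self.theta_minus = theta_minus
        self.theta_plus = theta_plus
        self.max_epochs = max_epochs
        self.init_sigma = init_sigma

    def _activation(self, centers, sigmas, x):
        if len(centers) == 0:
            return np.empty(0)
        d2 = np.sum((centers - x) ** 2, axis=1)
        return np.exp(-d2 / (2.0 * sigmas**2))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        centers = {c: np.empty((0, X.shape[1])) for c in self.classes_}
        sigmas = {c: np.empty(0) for c in self.classes_}
        weights = {c: np.empty(0) for c in self.classes_}
        shrink = np.sqrt(-2.0 * np.log(self.theta_minus))
        for _ in range(self.max_epochs):
            committed = False
            for c in self.classes_:
                weights[c] = np.zeros_like(weights[c])
            for x, c in zip(X, y):
                act = self._activation(centers[c], sigmas[c], x)
                if len(act) and act.max() >= self.theta_plus:
                    weights[c][np.argmax(act)] += 1.0
                else:
                    centers[c] = np.vstack([centers[c], x[None, :]])
                    sigmas[c] = np.append(sigmas[c], self.init_sigma)
                    weights[c] = np.append(weights[c], 1.0)
                    committed = True
                for other in self.classes_:
                    if other == c or len(centers[other]) == 0:
                        continue
                    dist = np.sqrt(np.sum((centers[other] - x) ** 2, axis=1))
                    limit = np.maximum(dist / shrink, 1e-12)
                    sigmas[other] = np.minimum(sigmas[other], limit)
            if not committed:
                break
        self.centers_, self.sigmas_, self.weights_ = centers, sigmas, weights
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "centers_")
        X = np.asarray(X, dtype=float)
        scores = np.zeros((len(X), len(self.classes_)))
        for j, c in enumerate(self.classes_):
            for i, x in enumerate(X):
                act = self._activation(self.centers_[c], self.sigmas_[c], x)
                scores[i, j] = float(self.weights_[c] @ act) if len(act) else 0.0
        totals = scores.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            proba = np.where(totals > 0, scores / totals, 1.0 / len(self.classes_))
        return proba

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class RotationForestClassifier(BaseEstimator, ClassifierMixin):
    """Rotation forest: decision trees on PCA-rotated feature subsets.

    For each tree the features are split into disjoint subsets; each subset
    is rotated by the principal components of a bootstrap sample, and a full
    decision tree is trained on the rotated data.  Class probabilities are
    averaged over trees.
    """

    def __init__(self, n_estimators: int = 10, n_subsets: int = 3,
                 sample_fraction: float = 0.75, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.n_subsets = n_subsets
        self.sample_fraction = sample_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.random_state)
        n, p = X.shape
        self.rotations_ = []
        self.trees_ = []
        for _ in range(self.n_estimators):
            perm = rng.permutation(p)
            subsets = np.array_split(perm, min(self.n_subsets, p))
            R = np.zeros((p, p))
            for sub in subsets:
                idx = rng.choice(n, size=max(int(self.sample_fraction * n), 2),
                                 replace=False)
                pca = PCA(n_components=len(sub), svd_solver="full")
                pca.fit(X[np.ix_(idx, sub)])
                R[np.ix_(sub, sub)] = pca.components_.T
            tree = DecisionTreeClassifier(
                random_state=int(rng.integers(2**31 - 1))
            ).fit(X @ R, y)
            self.rotations_.append(R)
            self.trees_.append(tree)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=float)
        proba = np.zeros((len(X), len(self.classes_)))
        for R, tree in zip(self.rotations_, self.trees_):
            p = tree.predict_proba(X @ R)
            cols = [list(tree.classes_).index(c) for c in self.classes_]
            proba += p[:, cols]
        return proba / len(self.trees_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class _StringLabelWrapper(BaseEstimator, ClassifierMixin):
    """Adapter for estimators that require integer-encoded class labels."""

    def __init__(self, inner):
        self.inner = inner

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        codes = np.searchsorted(self.classes_, y)
        self.inner_ = clone(self.inner).fit(X, codes)
        return self

    def predict(self, X):
        check_is_fitted(self, "inner_")
        return self.classes_[self.inner_.predict(X)]

    def predict_proba(self, X):
        check_is_fitted(self, "inner_")
        return self.inner_.predict_proba(X)


# ---------------------------------------------------------------------------
# Classifier registry (hyperparameters fixed at their pre-optimised values)

CLASSIFIER_SPECS: dict[str, ClassifierSpec] = {
    "GB": ClassifierSpec(
        "GB", {"n_estimators": 93, "max_depth": 7, "learning_rate": 0.186}
    ),
    "DT": ClassifierSpec("DT", {"min_samples_leaf": 6}),
    "RaF": ClassifierSpec(
        "RaF", {"n_estimators": 57, "max_depth": 20, "min_samples_leaf": 7}
    ),
    "XGB": ClassifierSpec(
        "XGB",
        {
            "max_leaves": 21,
            "learning_rate": 0.212,
            "gamma": 0.0,
            "reg_lambda": 100.0,
            "max_bin": 59,
        },
    ),
    "kNN": ClassifierSpec("kNN", {"n_neighbors": 3}, needs_scaling=True),
    "MLP": ClassifierSpec(
        "MLP",
        {"hidden_layer_sizes": (43, 43), "max_iter": 109},
        needs_scaling=True,
    ),
    # Polynomial-kernel SVM; the fitted kernel power 1.99 is rounded to the
    # nearest integer degree supported by the implementation.
    "SVM": ClassifierSpec(
        "SVM",
        {"kernel": "poly", "degree": 2, "gamma": 1.971, "coef0": 1.033},
        needs_scaling=True,
    ),
    "RoF": ClassifierSpec("RoF", {}),
    "PNN": ClassifierSpec(
        "PNN", {"theta_minus": 0.113, "theta_plus": 0.509, "max_epochs": 131}
    ),
}


def build_estimator(spec: ClassifierSpec, random_state: int = 0):
    """Instantiate the estimator behind a spec."""
    hp = dict(spec.hyperparameters)
    if spec.name == "GB":
        return GradientBoostingClassifier(random_state=random_state, **hp)
    if spec.name == "DT":
        return DecisionTreeClassifier(random_state=random_state, **hp)
    if spec.name == "RaF":
        return RandomForestClassifier(random_state=random_state, **hp)
    if spec.name == "XGB":
        try:
            from xgboost import XGBClassifier
        except ImportError as exc:  # pragma: no cover
            raise HarnessError(
                "the XGB classifier requires the optional xgboost dependency"
            ) from exc
        return _StringLabelWrapper(
            XGBClassifier(
                tree_method="hist",
                grow_policy="lossguide",
                random_state=random_state,
                **hp,
            )
        )
    if spec.name == "kNN":
        return KNeighborsClassifier(**hp)
    if spec.name == "MLP":
        return MLPClassifier(random_state=random_state, **hp)
    if spec.name == "SVM":
        return SVC(random_state=random_state, **hp)
    if spec.name == "RoF":
        return RotationForestClassifier(random_state=random_state, **hp)
    if spec.name == "PNN":
        return PNNClassifier(**hp)
    raise HarnessError(f"unknown classifier {spec.name!r}")


# ---------------------------------------------------------------------------
# CV machinery


def _validate_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    features = [c for c in FEATURE_NAMES if c in table.columns]
    if not features:
        raise HarnessError("table contains none of the expected feature columns")
    X = table[features].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise HarnessError("feature table contains missing or non-finite values")
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise HarnessError("both classes must be present")
    return X, y, features


def stratified_folds(
    labels: Sequence[str], cv: CVConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold split (train_idx, test_idx) pairs."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < cv.k:
        raise HarnessError(
            f"smallest class has {counts.min()} members; cannot form {cv.k} folds"
        )
    skf = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def minmax_scale(
    train_block: np.ndarray, eval_block: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Max-min normalisation fitted on the training block only.

    Training features map into [0, 1]; evaluation values are transformed
    with the same parameters and may fall outside [0, 1] (no clipping).
    Constant training features map to 0 everywhere.
    """
    train_block = np.asarray(train_block, dtype=float)
    eval_block = np.asarray(eval_block, dtype=float)
    lo = train_block.min(axis=0)
    span = train_block.max(axis=0) - lo
    safe = np.where(span > 0, span, 1.0)
    scale = lambda b: np.where(span > 0, (b - lo) / safe, 0.0)
    return scale(train_block), scale(eval_block)


def _positive_scores(estimator, X: np.ndarray) -> np.ndarray:
    """Score for the positive (No-Risk) class from any fitted estimator."""
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(X)
        idx = list(estimator.classes_).index(NO_RISK)
        return proba[:, idx]
    scores = estimator.decision_function(X)
    # decision_function is oriented towards classes_[1]
    return scores if estimator.classes_[1] == NO_RISK else -scores


def aucroc(scores: Sequence[float], labels: Sequence[str],
           positive: str = NO_RISK) -> float:
    """Area under the ROC curve as the pairwise ranking probability.

    Equals the probability that a random positive instance receives a higher
    score than a random negative one, counting ties as one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise HarnessError("AUCROC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, F-measure, specificity, sensitivity, precision, recall.

    No-Risk is the positive class.  A metric whose denominator is zero is
    reported as NaN (undefined), never as 0.
    """
    if cm.total == 0:
        raise HarnessError("empty confusion matrix")
    tp, fn, fp, tn = cm.n_nr_nr, cm.n_nr_r, cm.n_r_nr, cm.n_r_r

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    sensitivity = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    precision = ratio(tp, tp + fp)
    f_measure = ratio(2 * precision * sensitivity, precision + sensitivity)
    return {
        "accuracy": (tp + tn) / cm.total,
        "f_measure": f_measure,
        "specificity": specificity,
        "sensitivity": sensitivity,
        "precision": precision,
        "recall": sensitivity,
    }


def _cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    folds: list[tuple[np.ndarray, np.ndarray]],
    random_state: int,
) -> float:
    correct = 0
    for tr, te in folds:
        Xtr, Xte = X[tr], X[te]
        if spec.needs_scaling:
            Xtr, Xte = minmax_scale(Xtr, Xte)
        est = build_estimator(spec, random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xtr, y[tr])
            correct += int(np.sum(est.predict(Xte) == y[te]))
    return correct / len(y)


def backward_feature_elimination(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    cv: CVConfig,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> list[str]:
    """Greedy wrapper feature selection driven by the classifier's CV accuracy.

    Starting from all features, each round drops the feature whose removal
    yields the highest CV accuracy, as long as that accuracy does not fall
    below the current one; elimination stops when every candidate removal
    strictly decreases accuracy.  Returns the best subset encountered
    (smallest among accuracy ties); ties between candidate removals are
    broken by feature-name order.
    """
    X, y, features = _validate_table(table)
    if folds is None:
        folds = stratified_folds(y, cv)
    current = list(features)
    col = {f: i for i, f in enumerate(features)}

    def acc(subset: list[str]) -> float:
        return _cv_accuracy(X[:, [col[f] for f in subset]], y, spec, folds, cv.seed)

    current_acc = acc(current)
    best_subset, best_acc = list(current), current_acc
    while len(current) > 1:
        candidates = []
        for f in sorted(current):
            subset = [g for g in current if g != f]
            candidates.append((acc(subset), f, subset))
        best_cand = max(candidates, key=lambda c: c[0])  # first max: name order
        if best_cand[0] < current_acc:
            break
        current_acc, _, current = best_cand
        if current_acc >= best_acc:
            best_subset, best_acc = list(current), current_acc
    return best_subset


def run_cv_experiment(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    cv: CVConfig,
    use_bfe: bool = False,
    nested: bool = False,
) -> EvaluationReport:
    """Stratified k-fold evaluation of one classifier.

    Per fold: (optionally) select features, max-min scale if the model needs
    it (parameters fitted on the training fold only), fit, and predict the
    held-out fold.  All test-fold predictions are pooled into one confusion
    matrix; the reported metrics derive from that matrix and the pooled
    class scores.  With ``use_bfe`` and not ``nested``, BFE runs once on the
    full table before CV; ``nested`` re-runs it inside every training fold
    (slower, leakage-free).
    """
    X, y, features = _validate_table(table)
    folds = stratified_folds(y, cv)
    col = {f: i for i, f in enumerate(features)}

    selected = list(features)
    if use_bfe and not nested:
        selected = backward_feature_elimination(table, spec, cv, folds)

    y_pred = np.empty(len(y), dtype=object)
    scores = np.empty(len(y), dtype=float)
    per_fold = []
    for fold_i, (tr, te) in enumerate(folds):
        fold_features = selected
        if use_bfe and nested:
            fold_features = backward_feature_elimination(
                table.iloc[tr], spec, cv
            )
        idx = [col[f] for f in fold_features]
        Xtr, Xte = X[np.ix_(tr, idx)], X[np.ix_(te, idx)]
        if spec.needs_scaling:
            Xtr, Xte = minmax_scale(Xtr, Xte)
        est = build_estimator(spec, cv.seed)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(Xtr, y[tr])
        except Exception as exc:
            raise HarnessError(
                f"{spec.name} failed to fit on fold {fold_i}: {exc}"
            ) from exc
        y_pred[te] = est.predict(Xte)
        scores[te] = _positive_scores(est, Xte)
        per_fold.append(
            {
                "fold": fold_i,
                "n_test": len(te),
                "accuracy": float(np.mean(y_pred[te] == y[te])),
                "features": list(fold_features),
            }
        )

    cm = ConfusionMatrix.from_predictions(y, y_pred.astype(str))
    metrics = metrics_from_confusion(cm)
    metrics["aucroc"] = aucroc(scores, y)
    return EvaluationReport(
        classifier=spec.name,
        metrics=metrics,
        confusion=cm,
        selected_features=selected,
        per_fold=per_fold,
    )


def report_table(reports: Sequence[EvaluationReport], digits: int = 3) -> pd.DataFrame:
    """Classifier x metric summary table, rounded for reporting."""
    data = {r.classifier: [round(r.metrics[m], digits) for m in METRIC_NAMES]
            for r in reports}
    return pd.DataFrame(data, index=METRIC_NAMES)
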