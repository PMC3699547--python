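"""One-against-rest linear-SVM classification in a reduced embedding,
evaluated by leave-one-out cross-validation (LOOCV).

For a k-class problem, k binary linear SVMs are trained, the i-th with
class i positive and all other samples negative; a test point is assigned
to the class whose SVM produces the highest decision value (exact ties go
to the lowest class index in training order).  Under LOOCV every subject is
held out once and BOTH the dimensionality reduction (IDA or the PCA
baseline) and the SVMs are refit on the remaining N-1 subjects, so the
held-out subject leaks into nothing.  The embedding dimension d is chosen
by a grid search over LOOCV accuracy, mirroring the protocol of small-n
neuroimaging studies (note this selects d on the same accuracy it reports,
an optimistic protocol; an honest nested variant is available).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import ida
from .connectivity import ConnectivityDataset

__all__ = [
    "OvRClassifier",
    "CVReport",
    "train_ovr",
    "predict_ovr",
    "loocv",
    "grid_search_dimension",
    "pca_baseline_reducer",
    "DEFAULT_C",
]

logger = logging.getLogger(__name__)

#: SVM regularization constant (soft-margin penalty)
DEFAULT_C = 1.0


@dataclasses.dataclass
class OvRClassifier:
    """One-against-rest linear classifier bank.

    ``weights[k]``/``biases[k]`` define the decision function of class
    ``classes[k]`` against the rest in the embedding space.
    """

    classes: list[str]
    weights: np.ndarray  # (k, d)
    biases: np.ndarray  # (k,)
    C: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.weights.shape[0] != len(self.classes):
            raise ValueError("one decision function per class required")

    def decision_values(self, Z: np.ndarray) -> np.ndarray:
        """(k, M) matrix of real-valued SVM outputs for columns of Z."""
        Z = np.asarray(Z, dtype=float)
        if Z.shape[0] != self.weights.shape[1]:
            raise ValueError(
                f"embedding dimension {Z.shape[0]} does not match classifier "
                f"dimension {self.weights.shape[1]}"
            )
        return self.weights @ Z + self.biases[:, None]


def train_ovr(Z: np.ndarray, y, C: float = DEFAULT_C) -> OvRClassifier:
    """Train one linear SVM per class against the rest.

    ``Z`` is d x N (samples as columns).  Uses unweighted hinge loss; per-
    fold class imbalance is left as-is.
    """
    Z = np.asarray(Z, dtype=float)
    y = [str(v) for v in y]
    if Z.shape[1] != len(y):
        raise ValueError("one label per column required")
    classes = list(dict.fromkeys(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")
    y_arr = np.array(y)
    weights = np.zeros((len(classes), Z.shape[0]))
    biases = np.zeros(len(classes))
    for k, c in enumerate(classes):
        target = np.where(y_arr == c, 1, -1)
        svm = SVC(kernel="linear", C=C)
        svm.fit(Z.T, target)
        # libsvm orients the decision function by its internal class order
        sign = 1.0 if svm.classes_[1] == 1 else -1.0
        weights[k] = sign * svm.coef_.ravel()
        biases[k] = sign * float(svm.intercept_[0])
    return OvRClassifier(classes=classes, weights=weights, biases=biases, C=C)


def predict_ovr(clf: OvRClassifier, Z: np.ndarray) -> list[str]:
    """Assign each column of Z to the class with the highest SVM output;
    exact ties resolve to the lowest class index."""
    dv = clf.decision_values(np.atleast_2d(np.asarray(Z, dtype=float)))
    return [clf.classes[k] for k in np.argmax(dv, axis=0)]


# ---------------------------------------------------------------------------
# reducers


def pca_baseline_reducer(X: np.ndarray, d: int) -> np.ndarray:
    """Top-d principal axes of mean-centered data (columns = axes).

    ``X`` is P x N with samples as columns; returns P x d, variance-ordered.
    """
    X = np.asarray(X, dtype=float)
    p, n = X.shape
    if not 1 <= d <= min(p, n - 1):
        raise ValueError(f"d={d} must satisfy 1 <= d <= min(P, N-1) = {min(p, n - 1)}")
    Xc = X - X.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return u[:, :d]


@dataclasses.dataclass
class _FoldReducer:
    """Fitted reduction for one fold: projection matrix + optional model."""

    W: np.ndarray
    model: ida.IntrinsicModel | None = None

    def embed(self, X: np.ndarray) -> np.ndarray:
        return self.W.T @ X


def _fit_reducer(
    X: np.ndarray, y, d: int, reducer: str, epsilon: float | None
) -> _FoldReducer:
    if reducer == "ida":
        data = ida.LabeledSampleMatrix.from_arrays(X, y)
        model = ida.fit_ida(data, d, epsilon)
        return _FoldReducer(W=model.W, model=model)
    if reducer == "pca":
        return _FoldReducer(W=pca_baseline_reducer(X, d))
    raise ValueError(f"unknown reducer {reducer!r} (expected 'ida' or 'pca')")


# ---------------------------------------------------------------------------
# cross-validation


@dataclasses.dataclass
class CVReport:
    """Leave-one-out results: per-fold predictions, confusion matrix (rows =
    true classes, as percentages summing to 100), per-class and overall
    accuracy, and — when produced by the grid search — the
    accuracy-vs-dimension curve and the chosen d."""

    true_labels: list[str]
    predicted_labels: list[str]
    classes: list[str]
    d: int
    reducer: str
    fold_weights: np.ndarray | None = None  # (n_folds, k, d) embedding weights
    accuracy_curve: dict[int, float] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.true_labels)

    @property
    def overall_accuracy(self) -> float:
        correct = sum(t == p for t, p in zip(self.true_labels, self.predicted_labels))
        return correct / self.n_samples

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        out = {}
        for c in self.classes:
            idx = [k for k, t in enumerate(self.true_labels) if t == c]
            out[c] = sum(self.predicted_labels[k] == c for k in idx) / len(idx)
        return out

    def confusion_matrix(self) -> pd.DataFrame:
        """Row-normalized percentages: rows true classes, columns predicted."""
        mat = np.zeros((len(self.classes), len(self.classes)))
        pos = {c: k for k, c in enumerate(self.classes)}
        for t, p in zip(self.true_labels, self.predicted_labels):
            mat[pos[t], pos[p]] += 1
        mat = 100.0 * mat / mat.sum(axis=1, keepdims=True)
        return pd.DataFrame(mat, index=self.classes, columns=self.classes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reducer": self.reducer,
            "d": self.d,
            "classes": self.classes,
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "confusion_matrix_percent": self.confusion_matrix().to_dict(),
            "folds": [
                {"fold": k, "true": t, "predicted": p}
                for k, (t, p) in enumerate(
                    zip(self.true_labels, self.predicted_labels)
                )
            ],
            "accuracy_curve": (
                {str(k): v for k, v in self.accuracy_curve.items()}
                if self.accuracy_curve
                else None
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def confusion_to_tsv(self, path: str | Path) -> None:
        self.confusion_matrix().to_csv(path, sep="\t", float_format="%.1f")


def _check_loocv_args(n: int, n_classes: int, d: int) -> None:
    if n < n_classes + 1:
        raise ValueError("need at least one more sample than classes")
    if d > n - 2:
        raise ValueError(
            f"d={d} too large for LOOCV: training folds have {n - 1} samples, "
            f"so d must be at most N-2 = {n - 2}"
        )


def loocv(
    dataset: ConnectivityDataset,
    d: int,
    epsilon: float | None = None,
    C: float = DEFAULT_C,
    reducer: str = "ida",
    *,
    collect_fold_weights: bool = True,
) -> CVReport:
    """Leave-one-out evaluation with per-fold refit of reducer and SVMs."""
    X = dataset.features.T  # P x N
    y = [str(v) for v in dataset.labels]
    classes = list(dict.fromkeys(y))
    n = len(y)
    _check_loocv_args(n, len(classes), d)
    preds: list[str] = []
    fold_w = np.zeros((n, len(classes), d)) if collect_fold_weights else None
    for k in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k] = False
        red = _fit_reducer(X[:, mask], [y[j] for j in range(n) if mask[j]], d, reducer, epsilon)
        Z_train = red.embed(X[:, mask])
        clf = train_ovr(Z_train, [y[j] for j in range(n) if mask[j]], C)
        z_test = red.embed(X[:, [k]])
        preds.append(predict_ovr(clf, z_test)[0])
        if fold_w is not None:
            # align fold class order with the dataset-level class order
            for ci, c in enumerate(classes):
                fold_w[k, ci] = clf.weights[clf.classes.index(c)]
    return CVReport(
        true_labels=y,
        predicted_labels=preds,
        classes=classes,
        d=d,
        reducer=reducer,
        fold_weights=fold_w,
    )


def grid_search_dimension(
    dataset: ConnectivityDataset,
    d_min: int = 2,
    d_max: int = 88,
    epsilon: float | None = None,
    C: float = DEFAULT_C,
    reducer: str = "ida",
) -> CVReport:
    """LOOCV at every integer d in [d_min, d_max]; best d maximizes accuracy
    (smallest d on ties).  The grid ceiling is capped at N-2 with a warning
    when it exceeds what LOOCV folds admit.

    The per-fold reduction is fit once at the largest d and truncated for
    smaller d — valid because both IDA and PCA order their components, so
    the top-d columns of the d_max fit equal the d-dimensional fit.
    """
    X = dataset.features.T
    y = [str(v) for v in dataset.labels]
    classes = list(dict.fromkeys(y))
    n = len(y)
    if d_min < 1:
        raise ValueError("d_min must be at least 1")
    if d_max > n - 2:
        warnings.warn(
            f"grid ceiling {d_max} exceeds N-2 = {n - 2}; capping", stacklevel=2
        )
        d_max = n - 2
    if d_min > d_max:
        raise ValueError(f"empty dimension grid [{d_min}, {d_max}]")
    grid = list(range(d_min, d_max + 1))

    # one reducer fit per fold at d_max, shared across the whole grid
    fold_reducers: list[_FoldReducer] = []
    fold_train_labels: list[list[str]] = []
    for k in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k] = False
        labels_k = [y[j] for j in range(n) if mask[j]]
        fold_reducers.append(_fit_reducer(X[:, mask], labels_k, d_max, reducer, epsilon))
        fold_train_labels.append(labels_k)

    curve: dict[int, float] = {}
    best: tuple[float, int, list[str], np.ndarray | None] | None = None
    for d in grid:
        preds = []
        fold_w = np.zeros((n, len(classes), d))
        for k in range(n):
            mask = np.ones(n, dtype=bool)
            mask[k] = False
            W_d = fold_reducers[k].W[:, :d]
            Z_train = W_d.T @ X[:, mask]
            clf = train_ovr(Z_train, fold_train_labels[k], C)
            preds.append(predict_ovr(clf, W_d.T @ X[:, [k]])[0])
            for ci, c in enumerate(classes):
                fold_w[k, ci] = clf.weights[clf.classes.index(c)]
        acc = sum(t == p for t, p in zip(y, preds)) / n
        curve[d] = acc
        logger.info("grid d=%d accuracy=%.4f (%s)", d, acc, reducer)
        if best is None or acc > best[0]:
            best = (acc, d, preds, fold_w)
    assert best is not None
    _, best_d, best_preds, best_fold_w = best
    return CVReport(
        true_labels=y,
        predicted_labels=best_preds,
        classes=classes,
        d=best_d,
        reducer=reducer,
        fold_weights=best_fold_w,
        accuracy_curve=curve,
    )


def nested_grid_search(
    dataset: ConnectivityDataset,
    d_min: int = 2,
    d_max: int = 20,
    epsilon: float | None = None,
    C: float = DEFAULT_C,
    reducer: str = "ida",
) -> CVReport:
    """Honest nested variant: for each outer held-out subject, d is chosen
    by an inner LOOCV over the remaining N-1 subjects only.  Slower and
    typically lower than the flat grid search; off by default."""
    X = dataset.features.T
    y = [str(v) for v in dataset.labels]
    classes = list(dict.fromkeys(y))
    n = len(y)
    preds = []
    chosen = []
    for k in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k] = False
        inner = ConnectivityDataset(
            features=X[:, mask].T,
            labels=[y[j] for j in range(n) if mask[j]],
            edge_map=dataset.edge_map,
            region_names=dataset.region_names,
        )
        inner_rep = grid_search_dimension(
            inner, d_min, min(d_max, n - 3), epsilon, C, reducer
        )
        d_k = inner_rep.d
        chosen.append(d_k)
        red = _fit_reducer(X[:, mask], inner.labels, d_k, reducer, epsilon)
        clf = train_ovr(red.embed(X[:, mask]), inner.labels, C)
        preds.append(predict_ovr(clf, red.embed(X[:, [k]]))[0])
    report = CVReport(
        true_labels=y,
        predicted_labels=preds,
        classes=classes,
        d=int(np.median(chosen)),
        reducer=reducer,
    )
    return report
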