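"""Intrinsic discriminant analysis (IDA).

IDA is a supervised linear dimensionality reduction for the
small-sample-size regime (feature dimension P far larger than the number of
training samples N).  Every training sample x_ij (the j-th sample of class
i) is decomposed into three intrinsic components

    x_ij = m  +  (m_i - m)  +  (x_ij - m_i)

a common component shared by all samples (the global mean m), a
class-common component (the class mean m_i about the global mean), and an
individual difference.  Stacking the class-common deviations, weighted by
the square root of the class sizes, gives H_cc with

    S_cc = H_cc H_cc' = sum_i n_i (m_i - m)(m_i - m)'

the between-class (class-common) scatter, and stacking the individual
deviations gives H_ind with S_ind = H_ind H_ind' the within-class
(individual) scatter.  The transformation matrix W maximizes class-common
variation relative to individual variation; its columns solve the perturbed
generalized eigenproblem

    S_cc w = lambda (S_ind + eps I) w,

where the ridge eps > 0 makes the right-hand side invertible despite S_ind
being singular when N < P.  The top-d eigenvectors form W; interpreted over
connectivity edges its columns are called intrinsic connectomes.

All linear algebra is carried out in the span of the centered training
samples (rank at most N), so no P x P matrix is ever formed; this is exact
because both scatter operators map the span into itself and eigenvectors
with nonzero eigenvalue must lie inside it.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .connectivity import ConnectivityDataset, EdgeIndexMap

__all__ = [
    "LabeledSampleMatrix",
    "IntrinsicModel",
    "IntrinsicDecomposition",
    "class_statistics",
    "intrinsic_decompose",
    "fit_ida",
    "transform",
    "intrinsicconnectomes",
    "default_epsilon",
    "max_embedding_dimension",
]

#: relative ridge applied to the individual scatter (eps = RIDGE * mean
#: diagonal of S_ind); absolute fallback when S_ind vanishes entirely
DEFAULT_EPSILON_SCALE = 1e-4
EPSILON_FLOOR = 1e-8


def max_embedding_dimension(n_samples: int) -> int:
    """Largest admissible embedding dimension for a fit on ``n_samples``.

    The centered training samples span at most n - 1 directions, so d is
    capped at n - 1; an 89-subject study admits dimensions up to 88.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    return n_samples - 1


@dataclasses.dataclass
class LabeledSampleMatrix:
    """Training data with samples as columns, grouped contiguously by class.

    ``X`` is P x N (features x samples); ``y`` gives one class identifier
    per column and must be block-contiguous (all samples of a class
    adjacent).  Use :meth:`from_arrays` to rearrange arbitrary ordering.
    """

    X: np.ndarray
    y: list[str]
    class_order: list[str]
    class_sizes: dict[str, int]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.y):
            raise ValueError("X must be P x N with one label per column")
        if sum(self.class_sizes.values()) != len(self.y):
            raise ValueError("class sizes do not sum to N")
        # verify contiguous grouping in the declared class order
        expected = [c for c in self.class_order for _ in range(self.class_sizes[c])]
        if expected != list(self.y):
            raise ValueError("columns are not grouped contiguously by class")

    @classmethod
    def from_arrays(cls, X: np.ndarray, y) -> "LabeledSampleMatrix":
        """Rearrange columns so each class is contiguous (stable order of
        first appearance; sample order within a class preserved)."""
        X = np.asarray(X, dtype=float)
        y = [str(v) for v in y]
        if X.shape[1] != len(y):
            raise ValueError("one label per column required")
        class_order = list(dict.fromkeys(y))
        if len(class_order) < 1:
            raise ValueError("empty data")
        order = [k for c in class_order for k, lab in enumerate(y) if lab == c]
        sizes = {c: y.count(c) for c in class_order}
        return cls(X[:, order], [y[k] for k in order], class_order, sizes)

    @classmethod
    def from_dataset(cls, dataset: ConnectivityDataset) -> "LabeledSampleMatrix":
        return cls.from_arrays(dataset.features.T, dataset.labels)

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    @property
    def n_features(self) -> int:
        return self.X.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_order)


@dataclasses.dataclass
class IntrinsicDecomposition:
    """One sample's intrinsic components; they sum back to the sample."""

    common: np.ndarray
    class_common: np.ndarray
    individual: np.ndarray

    @property
    def reconstruction(self) -> np.ndarray:
        return self.common + self.class_common + self.individual


@dataclasses.dataclass
class IntrinsicModel:
    """Fitted IDA state.

    ``W`` is P x d with unit-norm columns (the intrinsic connectomes),
    ordered by non-increasing generalized eigenvalue; ``transform`` applies
    W'X.  Means are retained for the intrinsic decomposition and for
    diagnostics; ``epsilon`` is the ridge actually used.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    global_mean: np.ndarray
    class_means: dict[str, np.ndarray]
    epsilon: float
    d: int

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.W.shape[1] != self.d or self.eigenvalues.shape != (self.d,):
            raise ValueError("inconsistent model dimensions")
        if np.any(np.linalg.norm(self.W, axis=0) == 0):
            raise ValueError("zero column in transformation matrix")
        if np.any(np.diff(self.eigenvalues) > 1e-9 * (1 + abs(self.eigenvalues[0]))):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    def save(self, path: str | Path) -> None:
        """Serialize to a single portable .npz archive (exact round-trip)."""
        labels = list(self.class_means)
        np.savez(
            path,
            version=np.array(["connida-intrinsic-model-1"]),
            W=self.W,
            eigenvalues=self.eigenvalues,
            global_mean=self.global_mean,
            class_labels=np.array(labels),
            class_means=np.stack([self.class_means[c] for c in labels]),
            epsilon=np.array([self.epsilon]),
            d=np.array([self.d]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "IntrinsicModel":
        with np.load(path, allow_pickle=False) as z:
            if str(z["version"][0]) != "connida-intrinsic-model-1":
                raise ValueError("unrecognized model archive version")
            labels = [str(c) for c in z["class_labels"]]
            return cls(
                W=z["W"],
                eigenvalues=z["eigenvalues"],
                global_mean=z["global_mean"],
                class_means={c: z["class_means"][k] for k, c in enumerate(labels)},
                epsilon=float(z["epsilon"][0]),
                d=int(z["d"][0]),
            )


# ---------------------------------------------------------------------------
# scatter construction


def class_statistics(
    data: LabeledSampleMatrix, *, weight_by_size: bool = True
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Global/class means and the class-common and individual matrices.

    Returns ``(global_mean, class_means, H_cc, H_ind)`` where H_cc has one
    column per class — sqrt(n_i) (m_i - m) when ``weight_by_size`` (so that
    H_cc H_cc' is the standard between-class scatter), unweighted deviations
    otherwise — and H_ind has one column per sample, x_ij - m_i.
    """
    m = data.X.mean(axis=1)
    class_means: dict[str, np.ndarray] = {}
    cc_cols = []
    ind_cols = []
    start = 0
    for c in data.class_order:
        n_i = data.class_sizes[c]
        block = data.X[:, start : start + n_i]
        m_i = block.mean(axis=1)
        class_means[c] = m_i
        w = np.sqrt(n_i) if weight_by_size else 1.0
        cc_cols.append(w * (m_i - m))
        ind_cols.append(block - m_i[:, None])
        if n_i == 1:
            warnings.warn(
                f"class {c!r} has a single sample; it contributes only zero "
                "columns to the individual scatter",
                stacklevel=2,
            )
        start += n_i
    H_cc = np.column_stack(cc_cols)
    H_ind = np.concatenate(ind_cols, axis=1)
    return m, class_means, H_cc, H_ind


def intrinsic_decompose(
    x: np.ndarray, data: LabeledSampleMatrix, class_of_x: str
) -> IntrinsicDecomposition:
    """Split a sample into common + class-common + individual components."""
    if class_of_x not in data.class_order:
        raise ValueError(f"unknown class {class_of_x!r}")
    x = np.asarray(x, dtype=float)
    m, class_means, _, _ = class_statistics(data)
    m_i = class_means[class_of_x]
    return IntrinsicDecomposition(
        common=m, class_common=m_i - m, individual=x - m_i
    )


# ---------------------------------------------------------------------------
# fitting


def default_epsilon(H_ind: np.ndarray) -> float:
    """Scale-free ridge: 1e-4 times the mean diagonal of S_ind (its trace is
    the squared Frobenius norm of H_ind), with a small absolute floor."""
    p = H_ind.shape[0]
    mean_diag = float(np.sum(H_ind * H_ind)) / p
    if mean_diag <= 0:
        return EPSILON_FLOOR
    return DEFAULT_EPSILON_SCALE * mean_diag


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def fit_ida(
    data: LabeledSampleMatrix,
    d: int,
    epsilon: float | None = None,
    *,
    weight_by_size: bool = True,
) -> IntrinsicModel:
    """Fit the IDA transformation by the span-based generalized eigensolve.

    Parameters
    ----------
    data
        Class-grouped training matrix (P x N).
    d
        Embedding dimension, 1 <= d <= N - 1.
    epsilon
        Ridge added to the individual scatter; ``None`` selects the
        scale-free default.

    Notes
    -----
    The centered samples are orthonormalized (thin QR) to a basis Q of their
    span; both scatters are congruent to small r x r matrices there, and the
    perturbed generalized eigenproblem is solved densely in that basis.
    Eigenvectors are mapped back by Q and normalized to unit length, with
    signs fixed so the largest-magnitude component is positive.
    """
    n = data.n_samples
    if not 1 <= d <= max_embedding_dimension(n):
        raise ValueError(
            f"embedding dimension d={d} must satisfy 1 <= d <= N-1 = {n - 1}"
        )
    m, class_means, H_cc, H_ind = class_statistics(data, weight_by_size=weight_by_size)
    if epsilon is None:
        epsilon = default_epsilon(H_ind)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")

    # Orthonormal basis of span(X - m); H_cc and H_ind columns both live here.
    Q, _ = np.linalg.qr(data.X - m[:, None], mode="reduced")
    A = Q.T @ H_cc  # r x c
    B = Q.T @ H_ind  # r x N
    S_cc_r = A @ A.T
    S_ind_r = B @ B.T + epsilon * np.eye(Q.shape[1])
    eigval, eigvec = scipy.linalg.eigh(S_cc_r, S_ind_r)
    order = np.argsort(eigval)[::-1][:d]
    lam = eigval[order]
    if d < len(eigval):
        next_lam = np.sort(eigval)[::-1][d]
        scale = abs(lam[0]) + 1e-30
        # ties among the ~zero eigenvalues beyond rank(S_cc) <= c-1 are
        # structural, not degenerate; only warn on ties at nonzero lambda
        if abs(lam[-1] - next_lam) <= 1e-10 * scale and abs(lam[-1]) > 1e-8 * scale:
            warnings.warn(
                "generalized eigenvalue tie at the embedding cut; keeping the "
                "first computed basis",
                stacklevel=2,
            )
    W = Q @ eigvec[:, order]
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    W = _fix_signs(W)
    return IntrinsicModel(
        W=W,
        eigenvalues=lam,
        global_mean=m,
        class_means=class_means,
        epsilon=float(epsilon),
        d=d,
    )


def transform(model: IntrinsicModel, X: np.ndarray) -> np.ndarray:
    """Project columns of X (P x M) into the embedding: returns W'X (d x M)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != model.n_features:
        raise ValueError(
            f"X has {X.shape[0]} features, model expects {model.n_features}"
        )
    return model.W.T @ X


def eigen_residual(model: IntrinsicModel, data: LabeledSampleMatrix) -> float:
    """Max relative residual of S_cc w = lambda (S_ind + eps I) w over the
    fitted eigenpairs, computed with matrix-vector products only."""
    _, _, H_cc, H_ind = class_statistics(data)
    scale = float(np.sum(H_cc * H_cc)) + model.epsilon
    worst = 0.0
    for k in range(model.d):
        w = model.W[:, k]
        lam = model.eigenvalues[k]
        lhs = H_cc @ (H_cc.T @ w)
        rhs = lam * (H_ind @ (H_ind.T @ w) + model.epsilon * w)
        worst = max(worst, float(np.linalg.norm(lhs - rhs)) / scale)
    return worst


def trace_ratio_objective(
    W: np.ndarray, H_cc: np.ndarray, H_ind: np.ndarray, epsilon: float
) -> float:
    """tr(W' S_cc W) / tr(W' (S_ind + eps I) W) — the discriminant objective
    a projection is judged by; used by oracles and diagnostics."""
    num = float(np.sum((H_cc.T @ W) ** 2))
    den = float(np.sum((H_ind.T @ W) ** 2)) + epsilon * float(np.sum(W * W))
    return num / den


def intrinsicconnectomes(
    model: IntrinsicModel,
    edge_map: EdgeIndexMap,
    region_names: list[str] | None = None,
) -> list[pd.DataFrame]:
    """Edge-indexed loading tables, one per column of W (unit-normalized).

    Each table lists edge id, region pair and loading; suitable for export
    as TSV edge lists.
    """
    if model.n_features != len(edge_map):
        raise ValueError(
            f"model has {model.n_features} features, edge map has "
            f"{len(edge_map)} edges"
        )
    base = edge_map.to_frame(region_names)
    out = []
    for k in range(model.d):
        col = model.W[:, k]
        col = col / np.linalg.norm(col)
        tab = base.copy()
        tab["loading"] = col
        tab["component"] = k
        out.append(tab)
    return out
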