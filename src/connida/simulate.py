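"""Synthetic multi-group regional BOLD time-series generator.

Emulates a three-group resting-state study (e.g. patients with two distinct
diagnoses plus healthy controls) at the scale of a 116-region whole-brain
parcellation: each subject is a region x time matrix of correlated Gaussian
signals whose inter-regional correlation structure differs between groups on
a controlled set of edges.  The generator exists so that every downstream
stage — connectivity extraction, supervised dimensionality reduction,
cross-validated classification and discriminative-edge mapping — can be
exercised end-to-end with known ground truth.

The signal model for a subject of class k is

    y = L_k z + s * g 1_p + (nothing else),

where ``L_k`` is the Cholesky factor of the class correlation matrix,
``z`` is region-wise AR(1) noise with unit marginal variance, ``g`` is a
per-subject global time course shared by all regions with amplitude ``s``
(``global_signal_sd``), and a 6-parameter motion table (3 translations,
3 rotations) is drawn independently as smooth AR(1) drift.  There is no
hemodynamic forward model and no voxel level: the unit of simulation is the
regional mean time series.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SubjectRecord",
    "make_group_covariances",
    "simulate_subjects",
    "write_dataset",
    "session_volume_count",
    "default_region_names",
]

#: smallest admissible eigenvalue when repairing an indefinite target matrix
_PD_EIGENVALUE_FLOOR = 1e-6

#: AR(1) coefficient of the simulated motion drift (motion is slow)
_MOTION_AR = 0.9


def session_volume_count(duration_seconds: float, tr_seconds: float) -> int:
    """Number of volumes acquired in a session of the given duration.

    A 6-minute session at TR = 2 s yields 180 volumes.
    """
    if duration_seconds <= 0 or tr_seconds <= 0:
        raise ValueError("duration and TR must be positive")
    return int(duration_seconds // tr_seconds)


def default_region_names(n_regions: int) -> list[str]:
    """Synthetic region labels (``region_001`` ...); stands in for an atlas
    lookup table, which is not distributed with the package."""
    width = max(3, len(str(n_regions)))
    return [f"region_{i + 1:0{width}d}" for i in range(n_regions)]


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one synthetic multi-group study.

    Defaults mirror a typical clinical resting-state protocol: three groups
    of 19/32/38 subjects, 116 regions, 180 volumes at TR = 2 s.

    Parameters
    ----------
    n_subjects_per_class
        Mapping from class label to a positive subject count.
    n_regions, n_volumes, tr_seconds
        Acquisition geometry.
    base_correlation
        Either a scalar off-diagonal correlation shared by all region pairs,
        or a full ``n_regions x n_regions`` target correlation matrix.
    perturbed_edges
        List of ``(class_label, (i, j), delta)`` triples: the target
        correlation of regions ``i < j`` in that class is shifted by
        ``delta`` relative to the base matrix.
    ar_coefficient
        Temporal AR(1) coefficient of the regional noise, in ``[0, 1)``.
    global_signal_sd
        Amplitude of the shared per-subject global time course added to all
        regions (gives the global-signal regression step a real target).
    motion_sd
        Amplitude of the simulated motion-parameter drift.
    seed
        Master seed; per-subject streams are derived from it by spawn key so
        subject sets are reproducible under subsetting.
    """

    n_subjects_per_class: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"mdd": 19, "scz": 32, "hc": 38}
    )
    n_regions: int = 116
    n_volumes: int = 180
    tr_seconds: float = 2.0
    base_correlation: float | np.ndarray = 0.1
    perturbed_edges: list[tuple[str, tuple[int, int], float]] = dataclasses.field(
        default_factory=list
    )
    ar_coefficient: float = 0.3
    global_signal_sd: float = 0.5
    motion_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not self.n_subjects_per_class:
            raise ValueError("at least one class is required")
        for label, n in self.n_subjects_per_class.items():
            if n < 1:
                raise ValueError(f"class {label!r} has non-positive size {n}")
        if self.n_regions < 2:
            raise ValueError("need at least two regions")
        if self.n_volumes < 2:
            raise ValueError("need at least two volumes")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.global_signal_sd < 0 or self.motion_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")
        base = self._base_matrix()
        for label, (i, j), delta in self.perturbed_edges:
            if label not in self.n_subjects_per_class:
                raise ValueError(f"perturbed edge refers to unknown class {label!r}")
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions and i != j):
                raise ValueError(f"invalid region pair ({i}, {j})")
            target = base[i, j] + delta
            if not -1 < target < 1:
                raise ValueError(
                    f"perturbed correlation for edge ({i}, {j}) in class "
                    f"{label!r} is {target:.3f}, outside (-1, 1)"
                )

    def _base_matrix(self) -> np.ndarray:
        if np.isscalar(self.base_correlation):
            r = float(self.base_correlation)
            if not -1 < r < 1:
                raise ValueError("base correlation must lie in (-1, 1)")
            base = np.full((self.n_regions, self.n_regions), r)
            np.fill_diagonal(base, 1.0)
            return base
        base = np.asarray(self.base_correlation, dtype=float)
        if base.shape != (self.n_regions, self.n_regions):
            raise ValueError("base correlation matrix has wrong shape")
        return base.copy()

    @property
    def class_labels(self) -> list[str]:
        return list(self.n_subjects_per_class)

    @property
    def n_subjects(self) -> int:
        return sum(self.n_subjects_per_class.values())


@dataclasses.dataclass
class SubjectRecord:
    """One subject: region x time BOLD matrix, motion table, group label."""

    subject_id: str
    label: str
    timeseries: np.ndarray  # (n_regions, n_volumes)
    motion: np.ndarray  # (6, n_volumes)

    def __post_init__(self) -> None:
        self.timeseries = np.asarray(self.timeseries, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        if self.timeseries.ndim != 2:
            raise ValueError("timeseries must be a 2-D region x time matrix")
        if self.motion.shape != (6, self.timeseries.shape[1]):
            raise ValueError("motion table must be 6 x n_volumes")
        if not np.isfinite(self.timeseries).all() or not np.isfinite(self.motion).all():
            raise ValueError("non-finite values in subject record")


def _repair_positive_definite(matrix: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a small floor and re-normalize to unit diagonal.

    Deterministic repair for targets made indefinite by edge perturbation;
    off-perturbation entries may move slightly from their nominal values.
    """
    eigval, eigvec = np.linalg.eigh(matrix)
    if eigval[0] > _PD_EIGENVALUE_FLOOR:
        return matrix
    clipped = np.clip(eigval, _PD_EIGENVALUE_FLOOR, None)
    repaired = (eigvec * clipped) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def make_group_covariances(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-class region x region correlation target matrices.

    Starts from the base matrix, applies each class's edge deltas, then
    repairs positive definiteness by eigenvalue clipping if needed.  With no
    perturbed edges every class matrix equals the base matrix.
    """
    config.validate()
    base = config._base_matrix()
    base = _repair_positive_definite(base)
    out: dict[str, np.ndarray] = {}
    for label in config.class_labels:
        m = base.copy()
        for cls, (i, j), delta in config.perturbed_edges:
            if cls == label:
                m[i, j] += delta
                m[j, i] = m[i, j]
        out[label] = _repair_positive_definite(m)
    return out


def _subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    # Stable per-subject substream: depends only on master seed and subject
    # index, so removing subjects does not reshuffle the remainder.
    ss = np.random.SeedSequence(master_seed, spawn_key=(subject_index,))
    return np.random.Generator(np.random.PCG64(ss))


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int], phi: float) -> np.ndarray:
    """Row-wise AR(1) process with unit marginal variance."""
    n_rows, n_t = shape
    eps = rng.standard_normal((n_rows, n_t))
    if phi == 0:
        return eps
    out = np.empty_like(eps)
    out[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n_t):
        out[:, t] = phi * out[:, t - 1] + scale * eps[:, t]
    return out


def simulate_subjects(config: SimulationConfig) -> list[SubjectRecord]:
    """Draw the full subject list; deterministic given ``config.seed``."""
    config.validate()
    targets = make_group_covariances(config)
    chol: dict[str, np.ndarray] = {}
    for label, m in targets.items():
        try:
            chol[label] = np.linalg.cholesky(m)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - repair guards this
            raise np.linalg.LinAlgError(
                f"class {label!r} covariance not positive definite after repair"
            ) from exc

    records: list[SubjectRecord] = []
    index = 0
    for label in config.class_labels:
        for k in range(config.n_subjects_per_class[label]):
            rng = _subject_rng(config.seed, index)
            z = _ar1_noise(rng, (config.n_regions, config.n_volumes), config.ar_coefficient)
            ts = chol[label] @ z
            if config.global_signal_sd > 0:
                g = rng.standard_normal(config.n_volumes)
                ts = ts + config.global_signal_sd * g
            motion = config.motion_sd * _ar1_noise(rng, (6, config.n_volumes), _MOTION_AR)
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{index + 1:03d}_{label}",
                    label=label,
                    timeseries=ts,
                    motion=motion,
                )
            )
            index += 1
    return records


def planted_study_config(
    *,
    n_regions: int = 116,
    n_volumes: int = 180,
    class_sizes: dict[str, int] | None = None,
    n_shared_edges: int = 10,
    n_specific_per_class: int = 10,
    delta: float = 0.4,
    seed: int = 0,
) -> SimulationConfig:
    """Study configuration with planted convergent/divergent structure.

    Emulates a two-patient-groups-plus-controls design: the first two
    classes share ``n_shared_edges`` perturbed edges (convergent ground
    truth) and each carries ``n_specific_per_class`` private ones
    (divergent ground truth); the last class stays at the base correlation.
    Edge locations are drawn reproducibly from ``seed``.
    """
    if class_sizes is None:
        class_sizes = {"mdd": 19, "scz": 32, "hc": 38}
    labels = list(class_sizes)
    if len(labels) < 3:
        raise ValueError("planted study needs two patient classes plus controls")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(97,)))
    all_pairs = [(i, j) for i in range(n_regions) for j in range(i + 1, n_regions)]
    n_pick = n_shared_edges + 2 * n_specific_per_class
    chosen = rng.choice(len(all_pairs), size=n_pick, replace=False)
    edges: list[tuple[str, tuple[int, int], float]] = []
    for k in range(n_shared_edges):
        pair = all_pairs[chosen[k]]
        edges.append((labels[0], pair, delta))
        edges.append((labels[1], pair, delta))
    for k in range(n_specific_per_class):
        edges.append((labels[0], all_pairs[chosen[n_shared_edges + k]], delta))
        edges.append(
            (labels[1], all_pairs[chosen[n_shared_edges + n_specific_per_class + k]], delta)
        )
    return SimulationConfig(
        n_subjects_per_class=dict(class_sizes),
        n_regions=n_regions,
        n_volumes=n_volumes,
        base_correlation=0.1,
        perturbed_edges=edges,
        seed=seed,
    )


def planted_edge_ids(
    config: SimulationConfig, pairs: list[tuple[int, int]]
) -> tuple[set[int], dict[str, set[int]]]:
    """Ground-truth edge ids of a planted study: (shared, per-class specific)."""
    by_class: dict[str, set[int]] = {}
    index = {p: k for k, p in enumerate(pairs)}
    for cls, pair, _ in config.perturbed_edges:
        by_class.setdefault(cls, set()).add(index[tuple(sorted(pair))])
    if not by_class:
        return set(), {}
    shared = set.intersection(*by_class.values())
    return shared, {c: s - shared for c, s in by_class.items()}


def write_dataset(records: list[SubjectRecord], out_dir: str | Path) -> Path:
    """Write per-subject time-series and motion TSVs plus a manifest TSV.

    Layout matches what the connectivity reader expects: each time-series
    file is regions x volumes with region-name index, the motion file has
    6 whitespace-delimited columns (one row per volume, realignment-parameter
    dialect), and ``manifest.tsv`` lists subject_id, label, timeseries path
    and motion path relative to the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        ts_name = f"{rec.subject_id}_timeseries.tsv"
        mo_name = f"{rec.subject_id}_motion.txt"
        names = default_region_names(rec.timeseries.shape[0])
        pd.DataFrame(rec.timeseries, index=names).to_csv(
            out_dir / ts_name, sep="\t", header=False, float_format="%.10g"
        )
        np.savetxt(out_dir / mo_name, rec.motion.T, fmt="%.10g")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "timeseries": ts_name,
                "motion": mo_name,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
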