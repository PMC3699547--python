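"""Regional time series -> Pearson functional-connectivity feature vectors.

The pipeline stage order follows common resting-state practice: optional
discard of initial volumes (magnetic saturation), zero-phase Chebyshev
band-pass filtering (0.01-0.08 Hz by default), nuisance regression against
an intercept, the global mean signal (toggleable) and six motion parameters,
then Pearson correlation of every region pair.  With a 116-region
parcellation the feature vector has 116*115/2 = 6670 entries.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import SubjectRecord, default_region_names

__all__ = [
    "EdgeIndexMap",
    "ConnectivityDataset",
    "extract_regional_timeseries",
    "bandpass_filter",
    "regress_nuisance",
    "connectivity_vector",
    "compute_dataset",
    "load_nifti_subject",
    "read_motion_table",
    "read_manifest",
]

#: Chebyshev type-I band-pass design: order and passband ripple (dB).
FILTER_ORDER = 4
FILTER_RIPPLE_DB = 0.5

#: default band in Hz
DEFAULT_BAND = (0.01, 0.08)

#: volumes dropped at scan start (applied when the run has >= 20 volumes)
DEFAULT_DISCARD_VOLUMES = 5


@dataclasses.dataclass(frozen=True)
class EdgeIndexMap:
    """Enumeration of unordered region pairs as edge features.

    Edges are the upper triangle in row-major order: all pairs (0, j) for
    j = 1..p-1, then (1, j), ...  Region indices are 0-based internally;
    atlas labels remain 1-based in file I/O.
    """

    n_regions: int

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [
            (i, j)
            for i in range(self.n_regions)
            for j in range(i + 1, self.n_regions)
        ]

    def __len__(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    def triu_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.n_regions, k=1)

    def to_matrix(self, edge_values: np.ndarray) -> np.ndarray:
        """Rebuild a symmetric region x region matrix (unit diagonal) from an
        edge vector; inverse of :func:`connectivity_vector` off-diagonal."""
        edge_values = np.asarray(edge_values, dtype=float)
        if edge_values.shape != (len(self),):
            raise ValueError("edge vector length does not match edge map")
        m = np.eye(self.n_regions)
        iu, ju = self.triu_indices()
        m[iu, ju] = edge_values
        m[ju, iu] = edge_values
        return m

    def to_frame(self, region_names: list[str] | None = None) -> pd.DataFrame:
        names = region_names or default_region_names(self.n_regions)
        iu, ju = self.triu_indices()
        return pd.DataFrame(
            {
                "edge_id": np.arange(len(self)),
                "region_i": [names[i] for i in iu],
                "region_j": [names[j] for j in ju],
            }
        )


@dataclasses.dataclass
class ConnectivityDataset:
    """N x P edge-feature matrix with labels and the edge <-> pair map."""

    features: np.ndarray  # (n_subjects, n_edges), Pearson r in [-1, 1]
    labels: list[str]
    edge_map: EdgeIndexMap
    region_names: list[str]
    subject_ids: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != len(self.edge_map):
            raise ValueError("feature matrix width must equal edge-map length")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("one label per subject required")
        if not np.isfinite(self.features).all():
            raise ValueError("non-finite connectivity features")
        if np.abs(self.features).max(initial=0.0) > 1 + 1e-9:
            raise ValueError("Pearson features must lie in [-1, 1]")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{k + 1:03d}" for k in range(len(self.labels))]

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.features.shape[1]

    def to_tsv(self, features_path: str | Path, edge_map_path: str | Path | None = None) -> None:
        width = len(str(self.n_edges))
        cols = [f"edge_{k + 1:0{width}d}" for k in range(self.n_edges)]
        df = pd.DataFrame(self.features, columns=cols)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        df.to_csv(features_path, sep="\t", index=False, float_format="%.10g")
        if edge_map_path is not None:
            self.edge_map.to_frame(self.region_names).to_csv(
                edge_map_path, sep="\t", index=False
            )

    @classmethod
    def from_tsv(cls, features_path: str | Path) -> "ConnectivityDataset":
        df = pd.read_csv(features_path, sep="\t")
        feats = df.drop(columns=["subject_id", "label"]).to_numpy(float)
        p = feats.shape[1]
        n_regions = int(round((1 + np.sqrt(1 + 8 * p)) / 2))
        return cls(
            features=feats,
            labels=df["label"].astype(str).tolist(),
            edge_map=EdgeIndexMap(n_regions),
            region_names=default_region_names(n_regions),
            subject_ids=df["subject_id"].astype(str).tolist(),
        )


# ---------------------------------------------------------------------------
# volume-level extraction


def extract_regional_timeseries(
    volume_series: np.ndarray, atlas_labels: np.ndarray
) -> np.ndarray:
    """Mean BOLD time series per atlas region.

    Parameters
    ----------
    volume_series
        4-D array (x, y, z, time) of registered functional volumes.
    atlas_labels
        3-D integer array with positive region labels, 0 = background.

    Returns
    -------
    Region x time matrix; row k is the voxel average of label k+1.
    """
    volume_series = np.asarray(volume_series)
    atlas_labels = np.asarray(atlas_labels)
    if volume_series.ndim != 4:
        raise ValueError("volume series must be 4-D (x, y, z, t)")
    if atlas_labels.shape != volume_series.shape[:3]:
        raise ValueError("atlas and volume spatial dimensions differ")
    if not np.issubdtype(atlas_labels.dtype, np.integer):
        raise ValueError("atlas labels must be integers")
    max_label = int(atlas_labels.max())
    if max_label < 1:
        raise ValueError("atlas contains no positive labels")
    flat = volume_series.reshape(-1, volume_series.shape[3])
    lab = atlas_labels.reshape(-1)
    out = np.empty((max_label, volume_series.shape[3]))
    for k in range(1, max_label + 1):
        mask = lab == k
        if not mask.any():
            raise ValueError(f"atlas label {k} covers zero voxels")
        out[k - 1] = flat[mask].mean(axis=0)
    return out


def load_nifti_subject(
    func_path: str | Path, atlas_path: str | Path
) -> np.ndarray:
    """Extract regional time series from a 4-D NIfTI run and a label image."""
    import nibabel as nib

    img = nib.load(str(func_path))
    atlas = nib.load(str(atlas_path))
    labels = np.asarray(atlas.dataobj)
    labels = np.rint(labels).astype(int)
    return extract_regional_timeseries(np.asarray(img.dataobj, dtype=float), labels)


# ---------------------------------------------------------------------------
# temporal preprocessing


def _design_bandpass(low_hz: float, high_hz: float, tr_seconds: float):
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist = {nyquist:.4g} Hz for TR = {tr_seconds} s"
        )
    return signal.cheby1(
        FILTER_ORDER,
        FILTER_RIPPLE_DB,
        [low_hz / nyquist, high_hz / nyquist],
        btype="bandpass",
    )


def bandpass_filter(
    ts: np.ndarray,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    tr_seconds: float = 2.0,
) -> np.ndarray:
    """Zero-phase Chebyshev type-I band-pass, applied row-wise.

    Order 4 with 0.5 dB passband ripple, run forward-backward (``filtfilt``)
    so phase is preserved; the effective amplitude response is the squared
    magnitude of the single-pass design.
    """
    ts = np.asarray(ts, dtype=float)
    b, a = _design_bandpass(low_hz, high_hz, tr_seconds)
    min_len = 3 * (max(len(a), len(b)) - 1) + 1
    if ts.shape[-1] < min_len:
        raise ValueError(
            f"time series too short for the order-{FILTER_ORDER} band-pass "
            f"(need more than {min_len - 1} points)"
        )
    return signal.filtfilt(b, a, ts, axis=-1)


def bandpass_gain(freq_hz: float, low_hz: float, high_hz: float, tr_seconds: float) -> float:
    """Amplitude gain of the zero-phase band-pass at one frequency.

    Analytic frequency response of the designed filter, squared for the
    forward-backward pass; used as the oracle in filter tests.
    """
    b, a = _design_bandpass(low_hz, high_hz, tr_seconds)
    fs = 1.0 / tr_seconds
    _, h = signal.freqz(b, a, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)


def regress_nuisance(
    ts: np.ndarray,
    global_signal: np.ndarray | None = None,
    motion: np.ndarray | None = None,
) -> np.ndarray:
    """OLS residuals of each region against nuisance regressors.

    The design matrix holds an intercept, optionally the global mean signal,
    and optionally the 6 motion parameters.  Residuals are orthogonal to
    every design column.
    """
    ts = np.asarray(ts, dtype=float)
    n_t = ts.shape[-1]
    cols = [np.ones(n_t)]
    names = ["intercept"]
    if global_signal is not None:
        g = np.asarray(global_signal, dtype=float).ravel()
        if g.shape[0] != n_t:
            raise ValueError("global signal length differs from time series")
        cols.append(g)
        names.append("global_signal")
    if motion is not None:
        m = np.asarray(motion, dtype=float)
        if m.shape != (6, n_t):
            raise ValueError("motion table must be 6 x n_volumes")
        cols.extend(m)
        names.extend(f"motion_{k + 1}" for k in range(6))
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name which columns are linearly dependent on the preceding ones
        bad = []
        for k in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : k + 1]) == np.linalg.matrix_rank(design[:, :k]):
                bad.append(names[k])
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.T, rcond=None)
    return ts - (design @ beta).T


# ---------------------------------------------------------------------------
# correlation features


def connectivity_vector(ts: np.ndarray, edge_map: EdgeIndexMap) -> np.ndarray:
    """Pearson correlation of every region pair, vectorized per edge map."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] != edge_map.n_regions:
        raise ValueError(
            f"time series has {ts.shape[0]} regions, edge map expects "
            f"{edge_map.n_regions}"
        )
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 time points for correlation")
    sd = ts.std(axis=1)
    zero = np.flatnonzero(sd <= 1e-12 * (np.abs(ts).max(axis=1) + 1.0))
    if zero.size:
        raise ValueError(
            f"zero-variance time series for region index {zero[0]}; "
            "correlation undefined"
        )
    corr = np.corrcoef(ts)
    iu, ju = edge_map.triu_indices()
    return np.clip(corr[iu, ju], -1.0, 1.0)


def preprocess_timeseries(
    ts: np.ndarray,
    motion: np.ndarray | None,
    *,
    tr_seconds: float = 2.0,
    band: tuple[float, float] = DEFAULT_BAND,
    discard_volumes: int | None = None,
    global_signal_regression: bool = True,
    filter_before_regression: bool = True,
) -> np.ndarray:
    """Full per-subject temporal pipeline: discard, filter, nuisance-regress.

    ``discard_volumes=None`` applies the default discard (5 volumes) when the
    run has at least 20 volumes, otherwise none.  The global signal is the
    across-region mean of the (possibly filtered) series.  By default the
    band-pass precedes nuisance regression; the order can be swapped.
    """
    ts = np.asarray(ts, dtype=float)
    if motion is not None and not np.any(motion):
        motion = None  # all-zero table would be collinear with the intercept
    if discard_volumes is None:
        discard_volumes = DEFAULT_DISCARD_VOLUMES if ts.shape[1] >= 20 else 0
    if discard_volumes:
        ts = ts[:, discard_volumes:]
        if motion is not None:
            motion = np.asarray(motion, dtype=float)[:, discard_volumes:]

    def _regress(x: np.ndarray) -> np.ndarray:
        g = x.mean(axis=0) if global_signal_regression else None
        return regress_nuisance(x, global_signal=g, motion=motion)

    if filter_before_regression:
        ts = bandpass_filter(ts, band[0], band[1], tr_seconds)
        ts = _regress(ts)
    else:
        ts = _regress(ts)
        ts = bandpass_filter(ts, band[0], band[1], tr_seconds)
    return ts


def compute_dataset(
    records: list[SubjectRecord],
    *,
    tr_seconds: float = 2.0,
    band: tuple[float, float] = DEFAULT_BAND,
    discard_volumes: int | None = None,
    global_signal_regression: bool = True,
    filter_before_regression: bool = True,
    region_names: list[str] | None = None,
) -> ConnectivityDataset:
    """Run the temporal pipeline and correlation on every subject."""
    if not records:
        raise ValueError("no subject records")
    p = records[0].timeseries.shape[0]
    edge_map = EdgeIndexMap(p)
    feats = np.empty((len(records), len(edge_map)))
    for k, rec in enumerate(records):
        clean = preprocess_timeseries(
            rec.timeseries,
            rec.motion,
            tr_seconds=tr_seconds,
            band=band,
            discard_volumes=discard_volumes,
            global_signal_regression=global_signal_regression,
            filter_before_regression=filter_before_regression,
        )
        feats[k] = connectivity_vector(clean, edge_map)
    return ConnectivityDataset(
        features=feats,
        labels=[r.label for r in records],
        edge_map=edge_map,
        region_names=region_names or default_region_names(p),
        subject_ids=[r.subject_id for r in records],
    )


# ---------------------------------------------------------------------------
# file readers (manifest-driven)


def read_motion_table(path: str | Path) -> np.ndarray:
    """Read a 6-column whitespace-delimited motion-parameter file
    (one row per volume) into the internal 6 x time layout."""
    m = np.loadtxt(path)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, got shape {m.shape}")
    return m.T


def read_manifest(manifest_path: str | Path) -> list[SubjectRecord]:
    """Load subjects listed in a manifest TSV (subject_id, label, timeseries
    path, optional motion path; paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "label", "timeseries"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest missing columns {sorted(required - set(df.columns))}")
    base = manifest_path.parent
    records = []
    for row in df.itertuples(index=False):
        ts = pd.read_csv(base / row.timeseries, sep="\t", header=None, index_col=0)
        ts_mat = ts.to_numpy(float)
        if hasattr(row, "motion") and isinstance(row.motion, str):
            motion = read_motion_table(base / row.motion)
        else:
            motion = np.zeros((6, ts_mat.shape[1]))
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                label=str(row.label),
                timeseries=ts_mat,
                motion=motion,
            )
        )
    return records
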