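"""Back-projection of classifier weights to connectivity-edge space and
identification of the most discriminative connections.

Each one-against-rest linear SVM contributes one weight vector per LOOCV
fold, expressed in the embedding space.  Fold weights are averaged (no
normalization), then mapped back to edge space through the reduction
matrix, W w_emb, so that the composite decision direction satisfies
(W w_emb)' x = w_emb' (W' x) for every sample x.  The top fraction (5% by
default) of edges by absolute back-projected weight form a classifier's
consensus set; a region's weight is the number of consensus edges incident
to it.  Combining the two patient-vs-rest classifiers yields

* the convergent set — the intersection of their consensus sets, edges that
  help separate each patient group from everyone else; and
* the divergent set — the top fraction of the difference profile
  |w_A - w_B| over back-projected weights (convergent edges excluded),
  edges that pull the two patient groups apart.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CVReport
from .connectivity import ConnectivityDataset, EdgeIndexMap
from .ida import IntrinsicModel, LabeledSampleMatrix, fit_ida

__all__ = [
    "DiscriminativeMap",
    "average_fold_weights",
    "backproject_weights",
    "top_fraction_edges",
    "region_occurrence_weights",
    "convergent_divergent_sets",
    "build_discriminative_maps",
    "DEFAULT_TOP_FRACTION",
]

DEFAULT_TOP_FRACTION = 0.05


@dataclasses.dataclass
class DiscriminativeMap:
    """Per-classifier discriminative profile over connectivity edges."""

    classifier: str  # class label of the "one" in one-against-rest
    edge_weights: np.ndarray  # (P,) back-projected mean weights
    consensus_edges: list[int]  # top-fraction edge ids, |weight| descending
    region_weights: np.ndarray  # (n_regions,) occurrence counts
    edge_map: EdgeIndexMap
    fraction: float

    def edge_table(self, region_names: list[str] | None = None) -> pd.DataFrame:
        """Consensus edges with region pair, weight and rank."""
        frame = self.edge_map.to_frame(region_names)
        rows = frame.iloc[self.consensus_edges].copy()
        rows["weight"] = self.edge_weights[self.consensus_edges]
        rows["rank"] = np.arange(1, len(self.consensus_edges) + 1)
        rows["classifier"] = self.classifier
        return rows.reset_index(drop=True)


def average_fold_weights(fold_weights) -> np.ndarray:
    """Arithmetic mean of per-fold weight vectors (no prior normalization)."""
    if len(fold_weights) == 0:
        raise ValueError("no fold weights to average")
    arr = np.asarray(fold_weights, dtype=float)
    if arr.ndim != 2:
        raise ValueError("fold weights must be equal-length vectors")
    return arr.mean(axis=0)


def backproject_weights(model: IntrinsicModel | np.ndarray, w_embedded: np.ndarray) -> np.ndarray:
    """Map an embedding-space weight vector back to edge space: W w_emb.

    Accepts either a fitted model or a raw P x d projection matrix.  The
    result is the composite linear decision direction in the original
    space: (W w_emb)' x == w_emb' (W' x) for every x.
    """
    W = model.W if isinstance(model, IntrinsicModel) else np.asarray(model, dtype=float)
    w_embedded = np.asarray(w_embedded, dtype=float).ravel()
    if W.shape[1] != w_embedded.shape[0]:
        raise ValueError(
            f"weight vector has {w_embedded.shape[0]} entries, projection has "
            f"{W.shape[1]} columns"
        )
    return W @ w_embedded


def top_fraction_edges(edge_weights: np.ndarray, fraction: float = DEFAULT_TOP_FRACTION) -> list[int]:
    """Edge ids of the top ``floor(fraction * P)`` weights by absolute value.

    Ranked by |weight| descending; ties at the cutoff break by ascending
    edge id.  A negative weight is as discriminative as a positive one for
    a linear decision, so magnitude is what ranks.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    w = np.abs(np.asarray(edge_weights, dtype=float))
    count = int(np.floor(fraction * w.shape[0]))
    if count == 0:
        return []
    order = np.lexsort((np.arange(w.shape[0]), -w))
    return [int(i) for i in order[:count]]


def region_occurrence_weights(consensus_edges, edge_map: EdgeIndexMap) -> np.ndarray:
    """Per-region counts of incident consensus edges (sum = 2 x edges)."""
    iu, ju = edge_map.triu_indices()
    counts = np.zeros(edge_map.n_regions, dtype=int)
    n_edges = len(edge_map)
    for e in consensus_edges:
        if not 0 <= e < n_edges:
            raise ValueError(f"edge id {e} outside edge map of length {n_edges}")
        counts[iu[e]] += 1
        counts[ju[e]] += 1
    return counts


def convergent_divergent_sets(
    map_a: DiscriminativeMap,
    map_b: DiscriminativeMap,
    fraction: float | None = None,
    *,
    convergent_rule: str = "intersection",
    divergent_rule: str = "difference",
    require_sign_concordance: bool = True,
) -> tuple[list[int], list[int]]:
    """Convergent and divergent edge sets from two patient-vs-rest maps.

    Convergent: edges in both consensus sets (``intersection``; ``union``
    also available), by default further required to carry same-signed
    weights in the two classifiers — a genuinely convergent alteration
    shifts both patient groups away from the rest in the same direction,
    whereas an edge altered in only one group enters the other classifier's
    consensus with the opposite sign (the unaffected group sits on the far
    side of its decision boundary).  Divergent: top-fraction edges of
    |w_a - w_b| over the back-projected profiles, excluding convergent
    edges and zero-weight entries (``difference``; ``rank_sum`` ranks by
    the sum of the two |weight| ranks instead).
    """
    if map_a.edge_map.n_regions != map_b.edge_map.n_regions:
        raise ValueError("maps use different edge maps")
    fraction = fraction if fraction is not None else map_a.fraction
    set_a, set_b = set(map_a.consensus_edges), set(map_b.consensus_edges)
    if convergent_rule == "intersection":
        convergent = sorted(set_a & set_b)
    elif convergent_rule == "union":
        convergent = sorted(set_a | set_b)
    else:
        raise ValueError(f"unknown convergent rule {convergent_rule!r}")
    if require_sign_concordance:
        convergent = [
            e
            for e in convergent
            if np.sign(map_a.edge_weights[e]) == np.sign(map_b.edge_weights[e])
        ]

    if divergent_rule == "difference":
        profile = np.abs(map_a.edge_weights - map_b.edge_weights)
    elif divergent_rule == "rank_sum":
        # smaller rank-sum = jointly strong; invert so top_fraction picks it
        rank_a = np.argsort(np.argsort(-np.abs(map_a.edge_weights)))
        rank_b = np.argsort(np.argsort(-np.abs(map_b.edge_weights)))
        profile = -(rank_a + rank_b).astype(float)
        profile -= profile.min()  # keep non-negative magnitudes
    else:
        raise ValueError(f"unknown divergent rule {divergent_rule!r}")
    candidates = top_fraction_edges(profile, fraction)
    conv = set(convergent)
    divergent = [e for e in candidates if e not in conv and profile[e] > 0]
    return convergent, divergent


def build_discriminative_maps(
    dataset: ConnectivityDataset,
    report: CVReport,
    *,
    fraction: float = DEFAULT_TOP_FRACTION,
    epsilon: float | None = None,
    backproject_per_fold: bool = False,
) -> dict[str, DiscriminativeMap]:
    """Full-map construction from a LOOCV report carrying fold weights.

    Default route: average fold weights in embedding space, refit the
    reduction on all N samples at the report's d, back-project once.
    Alternative (``backproject_per_fold``): back-project each fold's weight
    vector with that fold's own projection, then average in edge space.
    """
    if report.fold_weights is None:
        raise ValueError("report carries no fold weights; rerun LOOCV with "
                         "collect_fold_weights=True")
    if report.reducer != "ida":
        raise ValueError("discriminative mapping is defined for the IDA reducer")
    X = dataset.features.T
    y = [str(v) for v in dataset.labels]
    maps: dict[str, DiscriminativeMap] = {}
    if backproject_per_fold:
        n = len(y)
        edge_profiles = {c: np.zeros(X.shape[0]) for c in report.classes}
        for k in range(n):
            mask = np.ones(n, dtype=bool)
            mask[k] = False
            data_k = LabeledSampleMatrix.from_arrays(
                X[:, mask], [y[j] for j in range(n) if mask[j]]
            )
            model_k = fit_ida(data_k, report.d, epsilon)
            for ci, c in enumerate(report.classes):
                edge_profiles[c] += backproject_weights(model_k, report.fold_weights[k, ci])
        for c in report.classes:
            edge_profiles[c] /= n
            maps[c] = _make_map(c, edge_profiles[c], dataset.edge_map, fraction)
        return maps

    full = fit_ida(LabeledSampleMatrix.from_arrays(X, y), report.d, epsilon)
    for ci, c in enumerate(report.classes):
        mean_w = average_fold_weights(report.fold_weights[:, ci, :])
        edge_w = backproject_weights(full, mean_w)
        maps[c] = _make_map(c, edge_w, dataset.edge_map, fraction)
    return maps


def _make_map(
    classifier: str, edge_weights: np.ndarray, edge_map: EdgeIndexMap, fraction: float
) -> DiscriminativeMap:
    consensus = top_fraction_edges(edge_weights, fraction)
    return DiscriminativeMap(
        classifier=classifier,
        edge_weights=edge_weights,
        consensus_edges=consensus,
        region_weights=region_occurrence_weights(consensus, edge_map),
        edge_map=edge_map,
        fraction=fraction,
    )


# ---------------------------------------------------------------------------
# exports


def export_maps(
    maps: dict[str, DiscriminativeMap],
    out_dir: str | Path,
    region_names: list[str] | None = None,
    convergent: list[int] | None = None,
    divergent: list[int] | None = None,
) -> None:
    """Write per-classifier edge reports (TSV + JSON), region-weight tables,
    and optional convergent/divergent edge lists with region annotations."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    some_map = next(iter(maps.values()))
    frame = some_map.edge_map.to_frame(region_names)
    for c, m in maps.items():
        tab = m.edge_table(region_names)
        tab.to_csv(out_dir / f"consensus_edges_{c}.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"region": range(1, m.edge_map.n_regions + 1), "weight": m.region_weights}
        ).to_csv(out_dir / f"region_weights_{c}.tsv", sep="\t", index=False)
        payload = {
            "classifier": c,
            "fraction": m.fraction,
            "consensus_edges": list(map(int, m.consensus_edges)),
        }
        (out_dir / f"consensus_edges_{c}.json").write_text(json.dumps(payload, indent=2))
    for name, edges in (("convergent", convergent), ("divergent", divergent)):
        if edges is None:
            continue
        rows = frame.iloc[list(edges)].copy()
        rows.to_csv(out_dir / f"{name}_edges.tsv", sep="\t", index=False)


def export_graph(
    m: DiscriminativeMap, path: str | Path, region_names: list[str] | None = None
) -> None:
    """Consensus set as a GML text graph for external network viewers."""
    import networkx as nx

    names = region_names or [
        f"region_{i + 1:03d}" for i in range(m.edge_map.n_regions)
    ]
    iu, ju = m.edge_map.triu_indices()
    g = nx.Graph()
    for i, name in enumerate(names):
        if m.region_weights[i] > 0:
            g.add_node(name, weight=int(m.region_weights[i]))
    for e in m.consensus_edges:
        g.add_edge(names[iu[e]], names[ju[e]], weight=float(abs(m.edge_weights[e])))
    nx.write_gml(g, str(path))
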