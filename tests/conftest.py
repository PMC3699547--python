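import numpy as np
import pytest

from connida import SimulationConfig, compute_dataset, simulate_subjects


def planted_config(
    *,
    n_regions: int = 30,
    n_volumes: int = 180,
    sizes=(10, 10, 10),
    n_shared_edges: int = 8,
    n_specific_per_class: int = 4,
    delta: float = 0.4,
    seed: int = 7,
) -> SimulationConfig:
    """Three-group config mimicking a two-patient-groups-plus-controls study.

    Classes ``a`` and ``b`` (the "patient" groups) share ``n_shared_edges``
    perturbed edges and each additionally carries ``n_specific_per_class``
    private ones; class ``c`` stays at the base correlation everywhere.
    """
    rng = np.random.default_rng(seed)
    all_pairs = [(i, j) for i in range(n_regions) for j in range(i + 1, n_regions)]
    n_pick = n_shared_edges + 2 * n_specific_per_class
    chosen = rng.choice(len(all_pairs), size=n_pick, replace=False)
    edges = []
    for k in range(n_shared_edges):
        pair = all_pairs[chosen[k]]
        edges.append(("a", pair, delta))
        edges.append(("b", pair, delta))
    for k in range(n_specific_per_class):
        edges.append(("a", all_pairs[chosen[n_shared_edges + k]], delta))
        edges.append(
            ("b", all_pairs[chosen[n_shared_edges + n_specific_per_class + k]], delta)
        )
    return SimulationConfig(
        n_subjects_per_class=dict(zip(["a", "b", "c"], sizes)),
        n_regions=n_regions,
        n_volumes=n_volumes,
        base_correlation=0.1,
        perturbed_edges=edges,
        ar_coefficient=0.3,
        global_signal_sd=0.5,
        motion_sd=0.05,
        seed=seed,
    )


def planted_edge_ids(cfg, edge_map):
    """Planted structure as edge ids: (shared set, per-class specific sets)."""
    pairs = edge_map.pairs
    by_class: dict[str, set[int]] = {}
    for cls, pair, _ in cfg.perturbed_edges:
        by_class.setdefault(cls, set()).add(pairs.index(tuple(sorted(pair))))
    labels = sorted(by_class)
    shared = set.intersection(*(by_class[c] for c in labels)) if by_class else set()
    specific = {c: by_class[c] - shared for c in labels}
    return shared, specific


@pytest.fixture(scope="session")
def planted_dataset():
    """Connectivity dataset with shared + class-specific edge effects
    (session-scoped; building it runs the whole simulate+connectivity
    front end)."""
    cfg = planted_config()
    return compute_dataset(simulate_subjects(cfg)), cfg
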