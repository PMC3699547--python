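"""Run configuration and the end-to-end pipeline:
simulate -> connectivity -> classify -> discriminative maps.

Configuration is a flat YAML document validated at load; the resolved
config is copied into every run directory for provenance.  Outputs are
written to a temporary directory and moved into place only on success, so
a failed run leaves no partial artifacts at the target path.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import tempfile
import time
from pathlib import Path

import numpy as np
import yaml

from . import classify, connectivity, discriminative, simulate

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """All knobs of one reproducible run; round-trips through YAML."""

    # inputs: either a manifest of existing subjects or a simulation request
    manifest: str | None = None
    simulate: bool = True
    n_subjects_per_class: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"mdd": 19, "scz": 32, "hc": 38}
    )
    n_regions: int = 116
    n_volumes: int = 180
    tr_seconds: float = 2.0
    base_correlation: float = 0.1
    perturbed_edges: list = dataclasses.field(default_factory=list)
    ar_coefficient: float = 0.3
    global_signal_sd: float = 0.5
    motion_sd: float = 0.05

    # preprocessing
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    discard_volumes: int | None = None
    global_signal_regression: bool = True
    filter_before_regression: bool = True

    # reduction + classification
    reducer: str = "ida"
    epsilon: float | None = None
    d: int | None = None  # fixed dimension; None -> grid search
    d_min: int = 2
    d_max: int = 88
    svm_c: float = 1.0
    top_fraction: float = 0.05

    seed: int = 0

    def validate(self) -> None:
        if not self.simulate and not self.manifest:
            raise ValueError("either simulate=true or a manifest path is required")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.reducer not in ("ida", "pca"):
            raise ValueError("reducer must be 'ida' or 'pca'")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive when given")
        if self.d is not None and self.d < 1:
            raise ValueError("d must be a positive integer")
        if self.d_min < 1 or self.d_max < self.d_min:
            raise ValueError("invalid dimension grid")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def simulation_config(self) -> simulate.SimulationConfig:
        edges = [
            (str(cls_), (int(i), int(j)), float(delta))
            for cls_, (i, j), delta in (
                (e[0], tuple(e[1]), e[2]) for e in self.perturbed_edges
            )
        ]
        return simulate.SimulationConfig(
            n_subjects_per_class=dict(self.n_subjects_per_class),
            n_regions=self.n_regions,
            n_volumes=self.n_volumes,
            tr_seconds=self.tr_seconds,
            base_correlation=self.base_correlation,
            perturbed_edges=edges,
            ar_coefficient=self.ar_coefficient,
            global_signal_sd=self.global_signal_sd,
            motion_sd=self.motion_sd,
            seed=self.seed,
        )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and populate ``out_dir`` atomically.

    Writes: resolved config, subject data (if simulated), connectivity
    dataset + edge map TSVs, CVReport JSON + confusion TSV, discriminative
    edge/region TSVs, and a run log.  Deterministic under a fixed seed.
    """
    config.validate()
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        raise FileExistsError(f"output directory {out_dir} is not empty")
    t0 = time.time()
    tmp = Path(tempfile.mkdtemp(prefix="connida-run-", dir=out_dir.parent))
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(f"[{time.time() - t0:8.2f}s] {msg}")

    try:
        config.to_yaml(tmp / "config.yaml")
        if config.simulate:
            log("simulating subjects")
            records = simulate.simulate_subjects(config.simulation_config())
            simulate.write_dataset(records, tmp / "subjects")
        else:
            log(f"loading manifest {config.manifest}")
            records = connectivity.read_manifest(config.manifest)
        log(f"{len(records)} subjects loaded")

        dataset = connectivity.compute_dataset(
            records,
            tr_seconds=config.tr_seconds,
            band=(config.band_low_hz, config.band_high_hz),
            discard_volumes=config.discard_volumes,
            global_signal_regression=config.global_signal_regression,
            filter_before_regression=config.filter_before_regression,
        )
        dataset.to_tsv(tmp / "connectivity.tsv", tmp / "edge_map.tsv")
        log(f"connectivity dataset: {dataset.n_subjects} x {dataset.n_edges}")

        if config.d is not None:
            report = classify.loocv(
                dataset, config.d, config.epsilon, config.svm_c, config.reducer
            )
        else:
            report = classify.grid_search_dimension(
                dataset, config.d_min, config.d_max, config.epsilon,
                config.svm_c, config.reducer,
            )
        log(
            f"LOOCV ({config.reducer}) accuracy {100 * report.overall_accuracy:.1f}% "
            f"at d={report.d}"
        )
        report.to_json(tmp / "cv_report.json")
        report.confusion_to_tsv(tmp / "confusion_matrix.tsv")

        if config.reducer == "ida":
            maps = discriminative.build_discriminative_maps(
                dataset, report, fraction=config.top_fraction, epsilon=config.epsilon
            )
            patient_classes = [c for c in report.classes if c != "hc"]
            conv = div = None
            if len(patient_classes) >= 2:
                conv, div = discriminative.convergent_divergent_sets(
                    maps[patient_classes[0]], maps[patient_classes[1]]
                )
                log(
                    f"convergent edges: {len(conv)}, divergent edges: {len(div)}"
                )
            discriminative.export_maps(
                maps, tmp / "discriminative", dataset.region_names,
                convergent=conv, divergent=div,
            )

        (tmp / "run.log").write_text("\n".join(log_lines) + "\n")
        (tmp / "summary.json").write_text(
            json.dumps(
                {
                    "n_subjects": dataset.n_subjects,
                    "n_edges": dataset.n_edges,
                    "reducer": config.reducer,
                    "chosen_d": report.d,
                    "overall_accuracy": report.overall_accuracy,
                    "per_class_accuracy": report.per_class_accuracy,
                },
                indent=2,
                sort_keys=True,
            )
        )
        if out_dir.exists():
            out_dir.rmdir()
        shutil.move(str(tmp), str(out_dir))
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return out_dir
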