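"""End-to-end orchestration: simulate → segment → measure → stats.

Each stage reads its inputs from the run directory and writes its outputs
back there, so a single stage can be re-run from intermediate files and
reproduce the end-to-end result. A manifest lists every artifact with a
SHA-256 content hash; identical configuration and seed give identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from nanohcs import cytometry, dose_stats, segmentation
from nanohcs.images import read_field, write_label_map, read_label_map
from nanohcs.synthetic import EffectConfig, default_effect_config, generate_dose_series

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips losslessly through YAML."""

    effect: EffectConfig = field(default_factory=default_effect_config)
    fields_per_dose: int = 3
    nuclei_min_area: int = 30
    smoothing_sigma: float = 2.0
    spot_prominence: float = 50.0
    control_dose: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        # one global seed fans out to per-field seeds via the counter scheme
        self.effect.seed = int(self.seed)

    def to_dict(self) -> dict:
        return {
            "effect": self.effect.to_dict(),
            "fields_per_dose": self.fields_per_dose,
            "nuclei_min_area": self.nuclei_min_area,
            "smoothing_sigma": self.smoothing_sigma,
            "spot_prominence": self.spot_prominence,
            "control_dose": self.control_dose,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["effect"] = EffectConfig.from_dict(d["effect"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _load_config(run_dir: Path) -> RunConfig:
    return RunConfig.load(run_dir / "config.yaml")


def stage_simulate(run_dir: str | Path) -> None:
    run_dir = Path(run_dir)
    config = _load_config(run_dir)
    plate = generate_dose_series(config.effect, config.fields_per_dose)
    plate.write(run_dir)


def stage_segment(run_dir: str | Path) -> None:
    run_dir = Path(run_dir)
    config = _load_config(run_dir)
    layout = pd.read_csv(run_dir / "layout.csv")
    labels_dir = run_dir / "labels"
    for _, row in layout.iterrows():
        fid = row["field_id"]
        fimg = read_field(run_dir / "images", fid,
                          pixel_size=config.effect.pixel_size, dose=row["dose"])
        nuclei = segmentation.segment_nuclei(
            fimg["nuclear"], min_area=config.nuclei_min_area,
            smoothing_sigma=config.smoothing_sigma,
        )
        cells = segmentation.segment_cells(
            fimg["cyto_ros"], nuclei, smoothing_sigma=config.smoothing_sigma
        )
        write_label_map(nuclei, labels_dir / f"{fid}_nuclei.tif")
        write_label_map(cells, labels_dir / f"{fid}_cells.tif")


def stage_measure(run_dir: str | Path) -> None:
    run_dir = Path(run_dir)
    config = _load_config(run_dir)
    layout = pd.read_csv(run_dir / "layout.csv")
    tables = []
    for _, row in layout.iterrows():
        fid = row["field_id"]
        fimg = read_field(run_dir / "images", fid,
                          pixel_size=config.effect.pixel_size, dose=row["dose"])
        nuclei = read_label_map(run_dir / "labels" / f"{fid}_nuclei.tif", "nuclei")
        cells = read_label_map(run_dir / "labels" / f"{fid}_cells.tif", "cells")
        spots = segmentation.detect_spots(
            fimg["mito"], cells, prominence=config.spot_prominence
        )
        tables.append(cytometry.measure_cells(fimg, nuclei, cells, spots))
    pd.concat(tables, ignore_index=True).to_csv(run_dir / "cells.csv", index=False)


def stage_stats(run_dir: str | Path) -> None:
    run_dir = Path(run_dir)
    config = _load_config(run_dir)
    cells = pd.read_csv(run_dir / "cells.csv")
    summary, report = dose_stats.summarize_conditions(
        cells, control_dose=config.control_dose, seed=config.seed
    )
    summary.to_csv(run_dir / "summary.csv", index=False)
    (run_dir / "stats.json").write_text(json.dumps(report, indent=2))


STAGES = (
    ("simulate", stage_simulate),
    ("segment", stage_segment),
    ("measure", stage_measure),
    ("stats", stage_stats),
)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages into ``out_dir`` and return the artifact manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("nanohcs")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        config.save(out_dir / "config.yaml")
        for name, fn in STAGES:
            t0 = time.perf_counter()
            logger.info("stage %s starting", name)
            try:
                fn(out_dir)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(name, exc) from exc
            logger.info("stage %s done in %.1f s", name, time.perf_counter() - t0)
        manifest = build_manifest(out_dir)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()


def build_manifest(out_dir: str | Path) -> dict:
    """SHA-256 content hash for every artifact in the run directory."""
    out_dir = Path(out_dir)
    entries = {}
    for path in sorted(out_dir.rglob("*")):
        if not path.is_file() or path.name in ("manifest.json", "run.log"):
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        entries[str(path.relative_to(out_dir))] = digest
    seed = None
    cfg_path = out_dir / "config.yaml"
    if cfg_path.exists():
        seed = yaml.safe_load(cfg_path.read_text()).get("seed")
    return {"seed": seed, "artifacts": entries}
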