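"""Core image containers and TIFF I/O.

A microscope field is a set of co-registered 2D intensity channels indexed by
biological role. Channel roles map onto the filter names used by high-content
imagers and are encoded in file names when a field is written to disk:

====================  ==================  =========================
role                  filename suffix     stain emulated
====================  ==================  =========================
``nuclear``           ``_dapi``           Hoechst nuclear counterstain
``cyto_ros``          ``_fitc``           DCFDA ROS probe / autofluorescence
``mito``              ``_dsred``          MitoTracker Red CMXRos
``dead``              ``_cy5``            DRAQ7 dead-cell stain
====================  ==================  =========================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

CHANNEL_ROLES = ("nuclear", "cyto_ros", "mito", "dead")

ROLE_SUFFIX = {
    "nuclear": "dapi",
    "cyto_ros": "fitc",
    "mito": "dsred",
    "dead": "cy5",
}
SUFFIX_ROLE = {v: k for k, v in ROLE_SUFFIX.items()}


@dataclass
class FieldImage:
    """One microscope field: co-registered intensity channels by role.

    Parameters
    ----------
    channels : mapping of role -> 2D array
        At least ``nuclear`` and ``cyto_ros`` must be present for
        morphology-only runs; all four roles for the viability pipeline.
    pixel_size : float
        Lateral pixel size in µm/px.
    field_id : str
        Identifier unique within a plate.
    dose : float
        Nanoparticle dose the field was (virtually) exposed to, µg Fe/ml.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0
    field_id: str = "field"
    dose: float = 0.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for role, arr in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValueError(f"channel {role!r} is not 2D")
            if np.nanmin(arr) < 0:
                raise ValueError(f"channel {role!r} has negative intensities")
            self.channels[role] = arr
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]


@dataclass
class LabelMap:
    """Integer-labelled segmentation mask sharing a FieldImage's geometry.

    ``labels`` uses 0 for background and 1..K for objects; objects are
    8-connected regions and the label set is compact (no gaps).
    """

    labels: np.ndarray
    kind: str = "nuclei"  # "nuclei" | "cells"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label array must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label array must be integer typed")
        if self.kind not in ("nuclei", "cells"):
            raise ValueError(f"unknown LabelMap kind {self.kind!r}")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class SpotSet:
    """Punctate detections (mitochondrial spots) with cell ownership.

    ``table`` columns: ``row``, ``col`` (0-based pixel coordinates of the
    spot centroid), ``peak_intensity`` (raw channel value at the peak) and
    ``cell_label`` (owning cell in the cells LabelMap).
    """

    table: pd.DataFrame

    COLUMNS = ("row", "col", "peak_intensity", "cell_label")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"SpotSet table missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)

    def counts_by_cell(self) -> pd.Series:
        return self.table.groupby("cell_label").size()

    def mean_peak_by_cell(self) -> pd.Series:
        return self.table.groupby("cell_label")["peak_intensity"].mean()


def write_field(field_image: FieldImage, out_dir: str | Path) -> list[Path]:
    """Write one TIFF per channel using the role suffix naming convention."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for role in CHANNEL_ROLES:
        if role not in field_image.channels:
            continue
        path = out_dir / f"{field_image.field_id}_{ROLE_SUFFIX[role]}.tif"
        tifffile.imwrite(path, field_image.channels[role])
        paths.append(path)
    return paths


def read_field(
    directory: str | Path,
    field_id: str,
    pixel_size: float = 1.0,
    dose: float = 0.0,
) -> FieldImage:
    """Assemble a FieldImage from suffix-named per-channel TIFFs."""
    directory = Path(directory)
    channels: dict[str, np.ndarray] = {}
    for suffix, role in SUFFIX_ROLE.items():
        path = directory / f"{field_id}_{suffix}.tif"
        if path.exists():
            channels[role] = tifffile.imread(path)
    if not channels:
        raise FileNotFoundError(f"no channel TIFFs for field {field_id!r} in {directory}")
    return FieldImage(channels, pixel_size=pixel_size, field_id=field_id, dose=dose)


def write_label_map(label_map: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if label_map.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit storage")
    tifffile.imwrite(path, label_map.labels.astype(np.uint16))
    return path


def read_label_map(path: str | Path, kind: str) -> LabelMap:
    return LabelMap(tifffile.imread(path).astype(np.int32), kind=kind)
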