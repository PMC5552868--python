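"""Shared fixtures: a recovery plate with known dose effects, segmented and
measured once per session."""

from __future__ import annotations

import pandas as pd
import pytest

from nanohcs import cytometry, segmentation
from nanohcs.synthetic import EffectConfig, generate_dose_series


def recovery_config(seed: int = 20) -> EffectConfig:
    """Three-dose plate exercising the documented dose effects: dead fraction
    0 / 0.1 / 0.3, ROS induction ×1.5 at the middle dose, area shrink and
    elongation at the top dose; ≥500 cells per condition."""
    return EffectConfig(
        doses=[0.0, 50.0, 100.0],
        cells_per_field=170,
        field_shape=(1024, 1024),
        min_cells_per_dose=500,
        dead_fraction={0.0: 0.0, 50.0: 0.1, 100.0: 0.3},
        ros_scale={0.0: 1.0, 50.0: 1.5, 100.0: 1.0},
        area_scale={0.0: 1.0, 50.0: 1.0, 100.0: 0.8},
        axis_ratio={0.0: 0.6, 50.0: 0.5, 100.0: 0.45},
        seed=seed,
    )


def measure_plate(plate) -> pd.DataFrame:
    """Segment and measure every field of an in-memory plate."""
    tables = []
    for fimg in plate.fields:
        nuclei = segmentation.segment_nuclei(fimg["nuclear"])
        cells = segmentation.segment_cells(fimg["cyto_ros"], nuclei)
        spots = segmentation.detect_spots(fimg["mito"], cells)
        tables.append(cytometry.measure_cells(fimg, nuclei, cells, spots))
    return pd.concat(tables, ignore_index=True)


@pytest.fixture(scope="session")
def recovery_plate():
    config = recovery_config()
    plate = generate_dose_series(config, fields_per_dose=3)
    return plate


@pytest.fixture(scope="session")
def recovery_cells(recovery_plate) -> pd.DataFrame:
    return measure_plate(recovery_plate)
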