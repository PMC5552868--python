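"""Per-cell readouts: viability call, ROS intensity, mitochondrial health,
area and form factor.

The dead/alive call follows the far-red DNA-stain rule used in high-content
viability screens: a cell is dead when the mean dead-channel intensity over
its *nucleus* mask reaches 3× the image background (measuring over the
nucleus enforces the stain/nucleus co-localization structurally; the boundary
is included so the rule is a closed half-line). Background is the median of
all non-nuclear dead-channel pixels — the median keeps the estimate immune to
bright debris and saturated outliers.

Form factor is the minor/major axis ratio of the mask's intensity-equivalent
ellipse: 1 for a perfect circle, approaching 0 for a straight line, and
invariant to rotation (which a bounding-box width/length ratio would not be).
Mitochondrial intensity is the mean of detected spot peak values, not a
whole-cell channel mean, so it reports on the organelles rather than diffuse
background.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops

from nanohcs.images import FieldImage, LabelMap, SpotSet

logger = logging.getLogger(__name__)

CELL_COLUMNS = [
    "field_id",
    "dose",
    "cell_label",
    "nucleus_label",
    "nucleus_area_um2",
    "cell_area_um2",
    "form_factor",
    "ros_mean",
    "mito_count",
    "mito_mean_intensity",
    "dead_nuclear_mean",
    "background",
    "is_dead",
]


def estimate_background(dead_channel: np.ndarray, nuclei: LabelMap) -> float:
    """Median dead-channel intensity outside all nucleus masks (floor 1 count)."""
    img = np.asarray(dead_channel, dtype=float)
    if img.shape != nuclei.labels.shape:
        raise ValueError("channel and nuclei geometry differ")
    outside = nuclei.labels == 0
    if outside.mean() < 0.10:
        raise ValueError("fewer than 10% of pixels lie outside nuclei; "
                         "background estimate unreliable")
    return max(float(np.median(img[outside])), 1.0)


def classify_dead(dead_nuclear_mean: float, background: float) -> bool:
    """True iff the nuclear dead-stain mean reaches 3× background (inclusive)."""
    if background <= 0:
        raise ValueError("background must be positive")
    return dead_nuclear_mean >= 3.0 * background


def form_factor(cell_mask: np.ndarray) -> float:
    """Width-over-length of the mask's equivalent ellipse, in (0, 1]."""
    mask = np.asarray(cell_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = regionprops(mask.astype(np.uint8))[0]
    major = props.axis_major_length
    minor = props.axis_minor_length
    if major == 0:  # degenerate single pixel (or perfectly symmetric point)
        logger.warning("degenerate mask for form factor; returning 1.0")
        return 1.0
    return min(minor / major, 1.0)


def measure_cells(
    field: FieldImage,
    nuclei: LabelMap,
    cells: LabelMap,
    spots: SpotSet | None = None,
    background: float | None = None,
) -> pd.DataFrame:
    """One CellRecord row per surviving cell.

    Areas are converted to µm² via ``pixel_size²``. Each cell must contain
    exactly one whole nucleus (the seeded-segmentation containment
    invariant); a violation raises. When the field lacks a dead channel the
    viability columns are NaN/False and background is NaN.
    """
    lab_img = cells.labels
    if lab_img.shape != nuclei.labels.shape:
        raise ValueError("cells and nuclei geometry differ")
    for role in ("cyto_ros",):
        if role not in field.channels:
            raise ValueError(f"field lacks required channel {role!r}")
    px_area = field.pixel_size**2

    has_dead = "dead" in field.channels
    if has_dead:
        dead_img = np.asarray(field["dead"], dtype=float)
        if background is None:
            background = estimate_background(dead_img, nuclei)
    cyto_img = np.asarray(field["cyto_ros"], dtype=float)

    # nucleus bookkeeping: per-nucleus pixel counts for containment checks
    nuc_labels = nuclei.labels
    nuc_sizes = np.bincount(nuc_labels.ravel())

    spot_counts = spots.counts_by_cell() if spots is not None else pd.Series(dtype=int)
    spot_means = spots.mean_peak_by_cell() if spots is not None else pd.Series(dtype=float)

    records = []
    for lab, sl in enumerate(ndi.find_objects(lab_img), start=1):
        if sl is None:
            continue
        cell_mask = lab_img[sl] == lab
        inside = nuc_labels[sl][cell_mask]
        cand = np.unique(inside[inside > 0])
        contained = [
            int(n) for n in cand if np.count_nonzero(inside == n) == nuc_sizes[n]
        ]
        if len(contained) != 1:
            raise ValueError(
                f"cell {lab} contains {len(contained)} whole nuclei; "
                "nucleus⊆cell containment violated"
            )
        nuc_id = contained[0]
        nuc_mask_local = nuc_labels[sl] == nuc_id

        ros_mean = float(cyto_img[sl][cell_mask].mean())
        if has_dead:
            dead_mean = float(dead_img[sl][nuc_mask_local].mean())
            dead_flag = classify_dead(dead_mean, background)
        else:
            dead_mean, dead_flag = float("nan"), False

        n_spots = int(spot_counts.get(lab, 0))
        if n_spots == 0 and spots is not None:
            logger.debug("cell %d has no detected mitochondrial spots", lab)
        records.append(
            dict(
                field_id=field.field_id,
                dose=field.dose,
                cell_label=lab,
                nucleus_label=nuc_id,
                nucleus_area_um2=float(nuc_sizes[nuc_id]) * px_area,
                cell_area_um2=float(cell_mask.sum()) * px_area,
                form_factor=form_factor(cell_mask),
                ros_mean=ros_mean,
                mito_count=n_spots,
                mito_mean_intensity=float(spot_means.get(lab, 0.0)),
                dead_nuclear_mean=dead_mean,
                background=background if has_dead else float("nan"),
                is_dead=bool(dead_flag),
            )
        )
    return pd.DataFrame.from_records(records, columns=CELL_COLUMNS)
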