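"""Seeded nucleus/cell segmentation and mitochondrial spot detection.

The scheme follows the seed-channel logic of high-content imagers: nuclei are
segmented on the nuclear counterstain (Gaussian smoothing → Otsu threshold →
distance-transform markers → watershed, splitting touching nuclei); whole
cells are obtained by a watershed seeded from the nucleus labels over the
cytoplasm-channel foreground, with holes filled and border-touching cells
excluded together with their nuclei; mitochondrial spots are band-pass
(difference-of-Gaussians) local maxima kept only inside a cell mask.

Conventions used throughout: 8-connectivity, 0-based (row, col) pixel
coordinates, deterministic output for fixed input and parameters. Border
exclusion tests the *cell* mask against the field border, because the
morphology features downstream are cell-level.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from nanohcs.images import LabelMap, SpotSet

logger = logging.getLogger(__name__)


def segment_nuclei(
    nuclear_channel: np.ndarray,
    min_area: int = 30,
    smoothing_sigma: float = 2.0,
    marker_min_distance: int = 7,
) -> LabelMap:
    """Label nuclei on the nuclear-counterstain channel.

    Smoothed-intensity Otsu foreground, split into objects by a watershed on
    the negated distance transform with local-maximum markers; objects below
    ``min_area`` px² are dropped and labels compacted to 1..K.

    An empty or constant channel yields zero labels with a logged warning
    rather than an exception.
    """
    img = np.asarray(nuclear_channel, dtype=float)
    if img.size == 0:
        raise ValueError("empty nuclear channel")
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if np.ptp(img) == 0:
        logger.warning("constant nuclear channel: no nuclei segmented")
        return LabelMap(np.zeros(img.shape, dtype=np.int32), kind="nuclei",
                        provenance={"reason": "constant image"})
    smoothed = gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    fg = smoothed > threshold_otsu(smoothed)
    if not fg.any():
        logger.warning("no foreground above Otsu threshold")
        return LabelMap(np.zeros(img.shape, dtype=np.int32), kind="nuclei")
    distance = ndi.distance_transform_edt(fg)
    # smoothing collapses the flat ridge an elongated object produces in its
    # distance transform to a single maximum, so only genuinely touching
    # nuclei get split
    distance_s = gaussian(distance, sigma=2.0, preserve_range=True)
    peaks = peak_local_max(
        distance_s, min_distance=marker_min_distance,
        labels=cc_label(fg, connectivity=2), exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-distance, markers, mask=fg, connectivity=2)
    labels = _drop_small_and_compact(labels, min_area)
    return LabelMap(
        labels, kind="nuclei",
        provenance={"min_area": min_area, "smoothing_sigma": smoothing_sigma,
                    "marker_min_distance": marker_min_distance},
    )


def segment_cells(
    cyto_channel: np.ndarray,
    nuclei: LabelMap,
    smoothing_sigma: float = 2.0,
) -> LabelMap:
    """Assign cytoplasm foreground to cells by a nucleus-seeded watershed.

    Post-processing per the screening protocol: interior holes are filled,
    and any cell whose mask touches the image border is removed (its nucleus
    is thereby excluded from downstream per-cell measurement as well). A
    nucleus with no surrounding foreground keeps a cell equal to its nucleus
    mask and is flagged in the provenance.
    """
    img = np.asarray(cyto_channel, dtype=float)
    if img.shape != nuclei.labels.shape:
        raise ValueError("cytoplasm channel and nuclei geometry differ")
    if nuclei.n_objects == 0:
        return LabelMap(np.zeros(img.shape, dtype=np.int32), kind="cells",
                        provenance={"reason": "no nuclei"})
    smoothed = gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    if np.ptp(img) == 0:
        fg = np.zeros(img.shape, dtype=bool)
    else:
        fg = smoothed > threshold_otsu(smoothed)
    mask = fg | (nuclei.labels > 0)
    labels = watershed(-smoothed, nuclei.labels.astype(np.int32), mask=mask,
                       connectivity=2)

    nucleus_only: list[int] = []
    out = np.zeros_like(labels, dtype=np.int32)
    removed_border = []
    new_id = 0
    H, W = labels.shape
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        filled = ndi.binary_fill_holes(sub)
        # hole filling must not annex neighbouring cells
        filled &= ~((labels[sl] > 0) & ~sub)
        # bounding boxes are tight, so a bbox on the border means the mask
        # touches the border
        if (sl[0].start == 0 or sl[1].start == 0
                or sl[0].stop == H or sl[1].stop == W):
            removed_border.append(int(lab))
            continue
        nuc_area = int((nuclei.labels[sl] == lab).sum())
        if int(filled.sum()) == nuc_area:
            nucleus_only.append(int(lab))
            logger.warning("nucleus %d has no surrounding cytoplasm foreground", lab)
        new_id += 1
        out[sl][filled] = new_id
    return LabelMap(
        out, kind="cells",
        provenance={
            "smoothing_sigma": smoothing_sigma,
            "removed_border_labels": removed_border,
            "nucleus_only_labels": nucleus_only,
        },
    )


def detect_spots(
    mito_channel: np.ndarray,
    cells: LabelMap,
    sigma_small: float = 1.0,
    sigma_large: float = 3.0,
    prominence: float = 50.0,
    min_distance: int = 3,
) -> SpotSet:
    """Band-pass local-maxima spot detection restricted to cell masks.

    The difference-of-Gaussians response suppresses both the flat background
    and pixel noise; maxima below ``prominence`` in the band-pass image are
    ignored, and detections falling outside every cell mask are discarded.
    Peak intensity is the raw channel value at the detected maximum.
    """
    img = np.asarray(mito_channel, dtype=float)
    if img.shape != cells.labels.shape:
        raise ValueError("mitochondria channel and cells geometry differ")
    dog = gaussian(img, sigma_small, preserve_range=True) - gaussian(
        img, sigma_large, preserve_range=True
    )
    peaks = peak_local_max(
        dog, min_distance=min_distance, threshold_abs=prominence, exclude_border=False
    )
    rows_out, cols_out, peak_vals, owners = [], [], [], []
    for r, c in peaks:
        lab = int(cells.labels[r, c])
        if lab == 0:
            continue
        rows_out.append(int(r))
        cols_out.append(int(c))
        peak_vals.append(float(img[r, c]))
        owners.append(lab)
    table = pd.DataFrame(
        {"row": rows_out, "col": cols_out, "peak_intensity": peak_vals,
         "cell_label": owners}
    )
    return SpotSet(table)


def _drop_small_and_compact(labels: np.ndarray, min_area: int) -> np.ndarray:
    ids, counts = np.unique(labels, return_counts=True)
    keep = ids[(ids > 0) & (counts >= min_area)]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return remap[labels]
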