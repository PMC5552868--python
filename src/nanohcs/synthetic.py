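"""Synthetic fluorescence-microscopy plates and assay tables with ground truth.

The generator emulates the experimental design of a nanoparticle
biocompatibility screen on plated adherent stem cells: a dose series of iron
concentrations (untreated control included), several imaged fields per dose,
and four co-registered fluorescence channels per field — nuclear counterstain,
cytoplasm/ROS, mitochondrial spots, and a far-red dead-cell stain. Cells are
drawn as rotated ellipses (concentric nucleus, ~25% of the cell area), the
simplest shape family whose area and axis ratio are analytically known, so
that every downstream measurement can be tested against exact truth. Dose
effects enter through per-dose lookup tables: dead-cell fraction, a
multiplicative ROS intensity factor, a cell-area scale and a target
minor/major axis ratio.

Deliberately not modelled: optical point-spread functions, camera physics,
3D stacks and time-lapse. Intensities follow a 16-bit unsigned model with a
flat per-channel background plus additive Gaussian noise.

Assay-table generators produce the linear absorbance response of a
colourimetric iron standard curve and relaxation-time series whose rate
1/T is linear in iron concentration, both with additive noise and recorded
truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from skimage import draw

from nanohcs.images import FieldImage, write_field

DoseTable = Union[float, dict]

TRUTH_COLUMNS = [
    "field_id",
    "dose",
    "field_seed",
    "cell_label",
    "nucleus_label",
    "center_row",
    "center_col",
    "centroid_row",
    "centroid_col",
    "semi_major",
    "semi_minor",
    "rotation",
    "area_px",
    "nucleus_area_px",
    "axis_ratio",
    "is_dead",
    "ros_factor",
    "mito_count",
    "touches_border",
]


class PlacementError(RuntimeError):
    """Raised when the requested cell count cannot be placed without overlap."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could only place {achieved}/{requested} non-overlapping cells; "
            "reduce cells_per_field or enlarge field_shape"
        )


@dataclass
class EffectConfig:
    """Ground-truth dose effects and acquisition parameters for the generator.

    Dose-effect entries (``dead_fraction``, ``ros_scale``, ``area_scale``,
    ``axis_ratio``) are either a constant or a ``{dose: value}`` table covering
    every dose, so the configuration serializes losslessly to YAML/JSON.

    Intensity units are detector counts on a 16-bit scale. ``background_level``
    defaults to 500 counts with additive Gaussian noise of SD 20 — arbitrary
    but recorded here so every run is reproducible.
    """

    doses: list[float] = field(
        default_factory=lambda: [0.0, 5.0, 10.0, 50.0, 100.0, 150.0, 200.0, 250.0]
    )
    cells_per_field: int = 170
    dead_fraction: DoseTable = 0.02
    ros_scale: DoseTable = 1.0
    area_scale: DoseTable = 1.0
    axis_ratio: DoseTable = 0.6
    mito_count_mean: float = 6.0
    background_level: float = 500.0
    noise_sd: float = 20.0
    seed: int = 0
    field_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.65  # µm/px, declared default (not inferred)
    mean_cell_area: float = 1200.0  # px², before area_scale
    cell_area_cv: float = 0.15
    axis_ratio_jitter: float = 0.05
    ros_cell_cv: float = 0.05
    nuclear_intensity: float = 3000.0
    cyto_intensity: float = 1000.0
    mito_spot_intensity: float = 1500.0
    dead_intensity_factor: float = 4.0  # dead-nucleus mean as multiple of background
    dead_mito_dim: float = 0.2  # mito spot dimming in dead cells
    min_cells_per_dose: int = 500

    def __post_init__(self) -> None:
        self.doses = [float(d) for d in self.doses]
        if not any(d == 0.0 for d in self.doses):
            raise ValueError("doses must include the untreated control (dose 0)")
        if len(set(self.doses)) != len(self.doses):
            raise ValueError("duplicate doses")
        for dose in self.doses:
            df = self.dead_fraction_at(dose)
            if not 0.0 <= df <= 1.0:
                raise ValueError(f"dead_fraction({dose}) = {df} outside [0, 1]")
            ar = self.axis_ratio_at(dose)
            if not 0.0 < ar <= 1.0:
                raise ValueError(f"axis_ratio({dose}) = {ar} outside (0, 1]")
            for name in ("ros_scale", "area_scale"):
                v = _lookup(getattr(self, name), dose, name)
                if v <= 0:
                    raise ValueError(f"{name}({dose}) = {v} must be > 0")
        if self.background_level <= 0:
            raise ValueError("background_level must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.field_shape = tuple(int(s) for s in self.field_shape)

    def dead_fraction_at(self, dose: float) -> float:
        return _lookup(self.dead_fraction, dose, "dead_fraction")

    def ros_scale_at(self, dose: float) -> float:
        return _lookup(self.ros_scale, dose, "ros_scale")

    def area_scale_at(self, dose: float) -> float:
        return _lookup(self.area_scale, dose, "area_scale")

    def axis_ratio_at(self, dose: float) -> float:
        return _lookup(self.axis_ratio, dose, "axis_ratio")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["field_shape"] = list(self.field_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EffectConfig":
        d = dict(d)
        if "field_shape" in d:
            d["field_shape"] = tuple(d["field_shape"])
        for key in ("dead_fraction", "ros_scale", "area_scale", "axis_ratio"):
            if isinstance(d.get(key), dict):
                d[key] = {float(k): float(v) for k, v in d[key].items()}
        return cls(**d)


def _lookup(table: DoseTable, dose: float, name: str) -> float:
    if isinstance(table, dict):
        for k, v in table.items():
            if math.isclose(float(k), dose, abs_tol=1e-9):
                return float(v)
        raise KeyError(f"{name} table has no entry for dose {dose}")
    return float(table)


def default_effect_config(**overrides) -> EffectConfig:
    """Study conditions mirrored by the default demo.

    ROS induction (×1.3) only at 10 and 50 µg Fe/ml; cell area shrinking only
    above 100 µg Fe/ml; cells elongating (axis ratio dropping) above
    50 µg Fe/ml; a small flat dead-cell fraction at every dose.
    """
    base = dict(
        doses=[0.0, 5.0, 10.0, 50.0, 100.0, 150.0, 200.0, 250.0],
        dead_fraction=0.02,
        ros_scale={0.0: 1.0, 5.0: 1.0, 10.0: 1.3, 50.0: 1.3, 100.0: 1.0,
                   150.0: 1.0, 200.0: 1.0, 250.0: 1.0},
        area_scale={0.0: 1.0, 5.0: 1.0, 10.0: 1.0, 50.0: 1.0, 100.0: 1.0,
                    150.0: 0.85, 200.0: 0.8, 250.0: 0.75},
        axis_ratio={0.0: 0.6, 5.0: 0.6, 10.0: 0.6, 50.0: 0.6, 100.0: 0.5,
                    150.0: 0.5, 200.0: 0.45, 250.0: 0.45},
    )
    base.update(overrides)
    return EffectConfig(**base)


# ---------------------------------------------------------------------------
# field generation


def generate_field(
    config: EffectConfig, dose: float, field_seed: int
) -> tuple[FieldImage, pd.DataFrame]:
    """Render one multi-channel field at the given dose, with ground truth.

    Returns the FieldImage plus a truth table with one row per generated cell
    (ellipse parameters, painted areas, dead flag, ROS factor, realized
    mitochondrial spot count, border flag). Regeneration with the same seed is
    bit-identical.
    """
    dose = float(dose)
    if not any(math.isclose(d, dose, abs_tol=1e-9) for d in config.doses):
        raise ValueError(f"dose {dose} not in config.doses")
    H, W = config.field_shape
    if H < 256 or W < 256:
        raise ValueError("field dimensions must be at least 256×256 px")

    rng = np.random.default_rng(field_seed)
    bg = config.background_level
    dead_p = config.dead_fraction_at(dose)
    ros = config.ros_scale_at(dose)
    area_mu = config.mean_cell_area * config.area_scale_at(dose)
    ratio_mu = config.axis_ratio_at(dose)

    occupancy = np.zeros((H, W), dtype=bool)
    cells = []  # list of dicts with mask coords etc.

    n = config.cells_per_field
    want_border = n >= 20
    for i in range(n):
        on_border = want_border and i == 0
        placed = False
        for _attempt in range(100):
            area = rng.normal(area_mu, config.cell_area_cv * area_mu)
            area = max(area, 0.25 * area_mu)
            q = float(np.clip(rng.normal(ratio_mu, config.axis_ratio_jitter), 0.1, 1.0))
            a = math.sqrt(area / (math.pi * q))  # semi-major
            b = a * q
            angle = rng.uniform(0.0, math.pi)
            margin = a + 3.0
            if on_border:
                side = rng.integers(0, 4)
                t = rng.uniform(margin, (H if side < 2 else W) - margin)
                # centre closer to the edge than the minimal ellipse extent,
                # so the painted mask is always clipped by the field border
                off = rng.uniform(0.0, 0.4 * b)
                if side == 0:
                    r0, c0 = t, off
                elif side == 1:
                    r0, c0 = t, W - 1 - off
                elif side == 2:
                    r0, c0 = off, t
                else:
                    r0, c0 = H - 1 - off, t
            else:
                if H - 2 * margin <= 1 or W - 2 * margin <= 1:
                    continue
                r0 = rng.uniform(margin, H - 1 - margin)
                c0 = rng.uniform(margin, W - 1 - margin)
            # padded footprint enforces a >=3 px gap between neighbouring cells
            prr, pcc = draw.ellipse(r0, c0, a + 3.0, b + 3.0, shape=(H, W), rotation=angle)
            if occupancy[prr, pcc].any():
                continue
            rr, cc = draw.ellipse(r0, c0, a, b, shape=(H, W), rotation=angle)
            if rr.size == 0:
                continue
            occupancy[rr, cc] = True
            nrr, ncc = draw.ellipse(r0, c0, a / 2.0, b / 2.0, shape=(H, W), rotation=angle)
            touches = bool(
                (rr.min() == 0) or (cc.min() == 0) or (rr.max() == H - 1) or (cc.max() == W - 1)
            )
            cells.append(
                dict(
                    center=(r0, c0), a=a, b=b, angle=angle, rr=rr, cc=cc,
                    nrr=nrr, ncc=ncc, touches_border=touches,
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(requested=n, achieved=len(cells))

    # biology draws — one pass each, fixed order for determinism
    dead_flags = rng.random(len(cells)) < dead_p
    ros_factors = ros * np.clip(rng.normal(1.0, config.ros_cell_cv, len(cells)), 0.8, 1.2)
    spot_counts = rng.poisson(config.mito_count_mean, len(cells))

    nuclear = np.full((H, W), bg, dtype=float)
    cyto = np.full((H, W), bg, dtype=float)
    mito = np.full((H, W), bg, dtype=float)
    dead_ch = np.full((H, W), bg, dtype=float)

    records = []
    for i, cell in enumerate(cells):
        rr, cc, nrr, ncc = cell["rr"], cell["cc"], cell["nrr"], cell["ncc"]
        cyto[rr, cc] = config.cyto_intensity * ros_factors[i]
        nuclear[nrr, ncc] = config.nuclear_intensity
        if dead_flags[i]:
            dead_ch[nrr, ncc] = config.dead_intensity_factor * bg
        amp = config.mito_spot_intensity * (config.dead_mito_dim if dead_flags[i] else 1.0)
        placed_spots = _place_spots(
            rng, cell, int(spot_counts[i]), (H, W), min_sep=6.0
        )
        for (sr, sc) in placed_spots:
            _add_blob(mito, sr, sc, amp, sigma=1.5)
        records.append(
            dict(
                field_id="field",
                dose=dose,
                field_seed=int(field_seed),
                cell_label=i + 1,
                nucleus_label=i + 1,
                center_row=cell["center"][0],
                center_col=cell["center"][1],
                centroid_row=float(rr.mean()),
                centroid_col=float(cc.mean()),
                semi_major=cell["a"],
                semi_minor=cell["b"],
                rotation=cell["angle"],
                area_px=int(rr.size),
                nucleus_area_px=int(nrr.size),
                axis_ratio=cell["b"] / cell["a"],
                is_dead=bool(dead_flags[i]),
                ros_factor=float(ros_factors[i]),
                mito_count=len(placed_spots),
                touches_border=cell["touches_border"],
            )
        )

    channels = {}
    for role, img in (("nuclear", nuclear), ("cyto_ros", cyto), ("mito", mito), ("dead", dead_ch)):
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, img.shape)
        channels[role] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    truth = pd.DataFrame.from_records(records, columns=TRUTH_COLUMNS)
    image = FieldImage(channels, pixel_size=config.pixel_size, field_id="field", dose=dose)
    return image, truth


def _place_spots(rng, cell, count, shape, min_sep):
    """Sample up to `count` spot centres inside the cell ellipse, pairwise
    separated by min_sep px (bounded retries; realized count may be lower)."""
    H, W = shape
    r0, c0 = cell["center"]
    a, b, angle = cell["a"], cell["b"], cell["angle"]
    cos, sin = math.cos(angle), math.sin(angle)
    pts: list[tuple[float, float]] = []
    for _ in range(count):
        for _try in range(50):
            # uniform in the unit disk, mapped into the (slightly shrunk) ellipse
            u, v = rng.uniform(-1, 1), rng.uniform(-1, 1)
            if u * u + v * v > 1:
                continue
            dr = 0.8 * (a * u * cos - b * v * sin)
            dc = 0.8 * (a * u * sin + b * v * cos)
            sr, sc = r0 + dr, c0 + dc
            if not (2 <= sr < H - 2 and 2 <= sc < W - 2):
                continue
            if all((sr - pr) ** 2 + (sc - pc) ** 2 >= min_sep**2 for pr, pc in pts):
                pts.append((sr, sc))
                break
    return pts


def _add_blob(img, r0, c0, amplitude, sigma):
    rad = int(math.ceil(4 * sigma))
    H, W = img.shape
    r_lo, r_hi = max(0, int(r0) - rad), min(H, int(r0) + rad + 1)
    c_lo, c_hi = max(0, int(c0) - rad), min(W, int(c0) + rad + 1)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    img[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)
    )


def truth_cell_mask(row, shape: tuple[int, int]) -> np.ndarray:
    """Repaint a truth row's cell ellipse; used by segmentation-recovery tests."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.ellipse(
        row["center_row"], row["center_col"], row["semi_major"], row["semi_minor"],
        shape=shape, rotation=row["rotation"],
    )
    mask[rr, cc] = True
    return mask


def truth_nucleus_mask(row, shape: tuple[int, int]) -> np.ndarray:
    """Repaint a truth row's nucleus ellipse (concentric, half the semi-axes)."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.ellipse(
        row["center_row"], row["center_col"],
        row["semi_major"] / 2.0, row["semi_minor"] / 2.0,
        shape=shape, rotation=row["rotation"],
    )
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# plate generation


@dataclass
class PlateDataset:
    """In-memory plate: per-field images with matching truth and a layout table."""

    fields: list[FieldImage]
    truth: pd.DataFrame
    layout: pd.DataFrame
    config: EffectConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        images_dir = out_dir / "images"
        images_dir.mkdir(parents=True, exist_ok=True)
        for fi in self.fields:
            write_field(fi, images_dir)
        layout_path = out_dir / "layout.csv"
        truth_path = out_dir / "truth.csv"
        self.layout.to_csv(layout_path, index=False)
        self.truth.to_csv(truth_path, index=False)
        return {"images": images_dir, "layout": layout_path, "truth": truth_path}


def field_seed_for(config_seed: int, dose_index: int, replicate: int) -> int:
    """Fan a single plate seed out to per-field seeds by a fixed counter scheme."""
    ss = np.random.SeedSequence([int(config_seed), int(dose_index), int(replicate)])
    return int(ss.generate_state(1)[0]) % (2**31)


def generate_dose_series(config: EffectConfig, fields_per_dose: int = 3) -> PlateDataset:
    """Generate the full dose series with at least ``min_cells_per_dose`` cells
    per condition (extra fields are added when the requested replicate count
    would fall short, mirroring the study's minimum-cells-per-condition rule).
    """
    if fields_per_dose < 1:
        raise ValueError("fields_per_dose must be >= 1")
    per_dose = max(
        fields_per_dose,
        math.ceil(config.min_cells_per_dose / max(config.cells_per_field, 1)),
    )
    if per_dose > fields_per_dose:
        warnings.warn(
            f"extending to {per_dose} fields/dose to reach "
            f">={config.min_cells_per_dose} cells per condition",
            stacklevel=2,
        )
    fields: list[FieldImage] = []
    truths = []
    layout_rows = []
    for di, dose in enumerate(config.doses):
        for rep in range(per_dose):
            fs = field_seed_for(config.seed, di, rep)
            image, truth = generate_field(config, dose, fs)
            fid = f"d{di:02d}r{rep:02d}"
            image.field_id = fid
            truth["field_id"] = fid
            fields.append(image)
            truths.append(truth)
            layout_rows.append(
                dict(field_id=fid, dose=dose, replicate=rep, field_seed=fs,
                     n_cells=len(truth))
            )
    layout = pd.DataFrame(layout_rows)
    return PlateDataset(fields, pd.concat(truths, ignore_index=True), layout, config)


# ---------------------------------------------------------------------------
# assay tables


def generate_absorbance_table(
    slope: float,
    intercept: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear standard-curve absorbances A = intercept + slope·C + ε, ε~N(0,σ²),
    clipped at zero (a spectrophotometer reports non-negative absorbance)."""
    concentrations = np.asarray(concentrations, dtype=float)
    if (concentrations < 0).any():
        raise ValueError("concentrations must be non-negative")
    if slope <= 0:
        raise ValueError("slope must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, concentrations.shape) if noise_sd > 0 else 0.0
    absorbance = np.clip(intercept + slope * concentrations + eps, 0.0, None)
    return pd.DataFrame(
        {"concentration_ug_ml": concentrations, "absorbance": absorbance}
    )


def generate_relaxation_table(
    relaxivity: float,
    native_rate: float,
    concentrations_mM,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Relaxation times T = 1/(R0 + r·C + ε) for a linear rate response.

    ε is resampled per row (bounded retries) until the rate stays positive;
    configurations where positivity cannot be achieved are rejected.
    """
    concentrations_mM = np.asarray(concentrations_mM, dtype=float)
    if native_rate <= 0:
        raise ValueError("native_rate (R0) must be positive")
    if relaxivity < 0:
        raise ValueError("relaxivity must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rates = np.empty_like(concentrations_mM)
    for i, c in enumerate(concentrations_mM):
        clean = native_rate + relaxivity * c
        if clean <= 0:
            raise ValueError(f"non-positive noiseless rate at C={c}")
        rate = clean
        if noise_sd > 0:
            for _ in range(1000):
                rate = clean + rng.normal(0.0, noise_sd)
                if rate > 0:
                    break
            else:
                raise ValueError(
                    f"could not draw a positive rate at C={c} with noise_sd={noise_sd}"
                )
        rates[i] = rate
    return pd.DataFrame(
        {
            "concentration_mM": concentrations_mM,
            "T_s": 1.0 / rates,
            "true_relaxivity": relaxivity,
            "true_native_rate": native_rate,
        }
    )
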