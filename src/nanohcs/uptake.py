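"""Colourimetric iron-uptake quantification (Tiron assay math).

A catechol chelator complexes Fe³⁺ and absorbs at 480 nm; iron concentration
is read off an ordinary-least-squares standard curve by inverse prediction.
Absorbances above 1 fall outside the instrument's linear range and trigger a
warning rather than silently biasing the fit. Uptake efficiency is the ratio
of the iron mass recovered from the well to the iron mass offered during
incubation:

    uptake% = 100 · (pg_per_cell · n_cells) / (C_inc [µg/ml] · V [ml] · 10⁶ pg/µg)

The well-digestion protocol dilutes the lysate before the colour reaction;
since the overall dilution factor depends on the exact liquid-handling chain,
it is exposed as an explicit parameter of :func:`iron_per_cell` instead of a
hard-coded constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from nanohcs.linfit import LinearFit

PG_PER_UG = 1.0e6


class LinearRangeWarning(UserWarning):
    """Absorbance outside the spectrophotometer's linear range (A > 1)."""


def fit_standard_curve(concentrations, absorbances) -> LinearFit:
    """OLS standard curve A = intercept + slope·C.

    Requires at least three points spanning a positive concentration range.
    Emits :class:`LinearRangeWarning` when any absorbance exceeds 1.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    absorbances = np.asarray(absorbances, dtype=float)
    if concentrations.size < 3:
        raise ValueError("standard curve needs at least 3 points")
    if np.ptp(concentrations) == 0:
        raise ValueError("standard concentrations are constant")
    if (absorbances > 1.0).any():
        warnings.warn(
            "absorbance(s) > 1 are outside the linear range; "
            "the fitted curve may be unreliable",
            LinearRangeWarning,
            stacklevel=2,
        )
    return LinearFit.fit(concentrations, absorbances)


@dataclass(frozen=True)
class IronQuantification:
    concentration: float  # µg Fe/ml
    clipped: bool  # negative inverse prediction clipped to 0
    extrapolated: bool  # absorbance outside the fitted concentration range


def quantify_iron(absorbance: float, fit: LinearFit) -> IronQuantification:
    """Inverse prediction C = (A − intercept) / slope, clipped at zero."""
    if fit.slope <= 0:
        raise ValueError("standard-curve slope must be positive")
    conc = (absorbance - fit.intercept) / fit.slope
    clipped = conc < 0
    if clipped:
        conc = 0.0
    lo, hi = fit.x_range
    extrapolated = not (lo <= conc <= hi)
    return IronQuantification(float(conc), bool(clipped), bool(extrapolated))


def iron_per_cell(
    measured_conc: float,
    assay_volume_ml: float,
    n_cells: int,
    dilution_factor: float = 1.0,
) -> float:
    """Iron load per cell (pg) from the assay-read concentration.

    ``dilution_factor`` converts the assay-cuvette concentration back to the
    undiluted per-well amount; it depends on the digestion protocol's liquid
    handling and must be supplied by the user.
    """
    if assay_volume_ml <= 0 or n_cells <= 0 or dilution_factor <= 0:
        raise ValueError("volume, cell count and dilution factor must be positive")
    if measured_conc < 0:
        raise ValueError("measured concentration must be non-negative")
    total_ug = measured_conc * assay_volume_ml * dilution_factor
    return total_ug * PG_PER_UG / n_cells


@dataclass(frozen=True)
class UptakeResult:
    incubation_conc: float  # µg Fe/ml
    incubation_volume_ml: float
    n_cells: int
    pg_per_cell: float
    total_fe_pg: float
    measured_conc: float  # recovered iron expressed back as µg Fe/ml of the well
    uptake_percent: float
    uptake_percent_rounded: int


def uptake_percentage(
    pg_per_cell: float,
    n_cells: int,
    incubation_conc: float,
    incubation_volume_ml: float,
) -> UptakeResult:
    """Uptake efficiency: recovered iron mass over offered iron mass.

    Reported both raw and rounded to the nearest integer percent.
    """
    if n_cells <= 0 or incubation_conc <= 0 or incubation_volume_ml <= 0:
        raise ValueError("cells, concentration and volume must be positive")
    if pg_per_cell < 0:
        raise ValueError("pg_per_cell must be non-negative")
    total_fe_pg = pg_per_cell * n_cells
    offered_pg = incubation_conc * incubation_volume_ml * PG_PER_UG
    pct = 100.0 * total_fe_pg / offered_pg
    return UptakeResult(
        incubation_conc=float(incubation_conc),
        incubation_volume_ml=float(incubation_volume_ml),
        n_cells=int(n_cells),
        pg_per_cell=float(pg_per_cell),
        total_fe_pg=float(total_fe_pg),
        measured_conc=float(total_fe_pg / PG_PER_UG / incubation_volume_ml),
        uptake_percent=float(pct),
        uptake_percent_rounded=int(round(pct)),
    )
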