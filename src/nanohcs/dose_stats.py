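"""Per-dose aggregation, control normalization and many-to-one testing.

Metrics are normalized to the untreated (dose 0) control as
``100 × dose_mean / control_mean``. Viability is deliberately reported under
both conventions in circulation for dead-cell-stain screens: the relative
number of dead cells (dead fraction as % of the control's dead fraction) and
the relative live fraction (live % of control live %) — the two disagree
whenever the control has deaths, so both are emitted rather than hiding the
discrepancy.

Inference uses the field/well mean as the replicate unit (per-cell values
within a well are not independent replicates), with a one-way ANOVA followed
by Dunnett's many-to-one comparisons against the control; the critical values
come from the equicorrelated multivariate-t distribution. Significance stars
use strict-inequality bins: **** p<0.0001, *** p<0.001, ** p<0.01, * p<0.05,
otherwise ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))

#: per-cell metrics summarized by dose (column name -> report label)
CELL_METRICS = {
    "ros_mean": "ros",
    "mito_mean_intensity": "mito_intensity",
    "mito_count": "mito_count",
    "cell_area_um2": "area",
    "form_factor": "form_factor",
}


def star_label(p: float) -> str:
    """Map a p-value to its significance label (ns/*/**/***/****)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for threshold, label in STAR_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


def normalize_to_control(
    means: pd.Series | dict, control_dose: float = 0.0, metric: str = "metric"
) -> pd.Series:
    """Relative-to-control percentages: 100 × mean(dose) / mean(control)."""
    s = pd.Series(means, dtype=float)
    if control_dose not in s.index:
        raise ValueError(f"control dose {control_dose} missing for {metric}")
    control = s.loc[control_dose]
    if control == 0:
        raise ValueError(f"control mean for {metric!r} is zero; "
                         "relative percentages undefined")
    return 100.0 * s / control


@dataclass
class DunnettResult:
    """One-way ANOVA plus Dunnett many-to-one comparisons against control."""

    f_statistic: float
    anova_p: float
    control_dose: float
    doses: list[float]
    statistics: np.ndarray  # many-to-one t statistics
    p_adjusted: np.ndarray  # familywise-adjusted (multivariate-t)
    p_unadjusted: np.ndarray  # marginal two-sided t with pooled df
    df: int

    def p_for(self, dose: float) -> float:
        return float(self.p_adjusted[self.doses.index(dose)])


def anova_dunnett(
    groups: dict[float, np.ndarray], control_dose: float = 0.0, seed: int = 0
) -> DunnettResult:
    """Test every dose group against the shared control.

    ``groups`` maps dose to replicate values (field/well means). Requires at
    least two groups and at least two replicates per group.
    """
    if control_dose not in groups:
        raise ValueError(f"control dose {control_dose} missing")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    clean = {}
    for dose, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise ValueError(f"group {dose} has fewer than 2 replicates")
        clean[float(dose)] = vals
    control = clean[control_dose]
    doses = sorted(d for d in clean if d != control_dose)
    treatments = [clean[d] for d in doses]

    f_stat, anova_p = stats.f_oneway(control, *treatments)
    rng = np.random.default_rng(seed)  # used only for unbalanced designs
    res = stats.dunnett(*treatments, control=control, random_state=rng)
    n_total = sum(v.size for v in clean.values())
    df = n_total - len(clean)
    p_unadj = 2.0 * stats.t.sf(np.abs(res.statistic), df)
    return DunnettResult(
        f_statistic=float(f_stat),
        anova_p=float(anova_p),
        control_dose=float(control_dose),
        doses=doses,
        statistics=np.asarray(res.statistic, dtype=float),
        p_adjusted=np.asarray(res.pvalue, dtype=float),
        p_unadjusted=p_unadj,
        df=df,
    )


def summarize_conditions(
    cells: pd.DataFrame, control_dose: float = 0.0, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Aggregate a per-cell table into per-dose condition summaries.

    Returns a long-format summary (one row per dose × metric with n_cells,
    mean, SD over cells, relative-to-control %, Dunnett-adjusted p and star
    label) and a JSON-able stats report with the ANOVA results per metric.
    Doses with fewer than two fields get NaN p-values with a warning.
    """
    required = {"dose", "field_id", "is_dead"} | set(CELL_METRICS)
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"per-cell table missing columns {sorted(missing)}")
    if control_dose not in set(cells["dose"]):
        raise ValueError(f"control dose {control_dose} absent from data")

    doses = sorted(cells["dose"].unique())
    by_dose = cells.groupby("dose")
    n_cells = by_dose.size()

    rows = []
    report: dict = {"control_dose": control_dose, "metrics": {}}

    # --- intensity / morphology metrics -----------------------------------
    for col, label in CELL_METRICS.items():
        means = by_dose[col].mean()
        sds = by_dose[col].std(ddof=1)
        rel = normalize_to_control(means, control_dose, metric=label)
        p_by_dose = _dunnett_on_field_means(
            cells, col, control_dose, seed=seed, report=report, label=label
        )
        for dose in doses:
            p = p_by_dose.get(dose, float("nan"))
            rows.append(
                dict(
                    dose=dose, metric=label, n_cells=int(n_cells[dose]),
                    mean=float(means[dose]), sd=float(sds[dose]),
                    relative_pct=float(rel[dose]),
                    p_value=p, stars="" if np.isnan(p) else star_label(p),
                )
            )

    # --- viability ---------------------------------------------------------
    dead_frac = by_dose["is_dead"].mean()
    live_frac = 1.0 - dead_frac
    per_field = cells.groupby(["dose", "field_id"])["is_dead"].mean().reset_index()
    for label, series, transform in (
        ("viability_live", live_frac, lambda s: 1.0 - s),
        ("dead_cells", dead_frac, lambda s: s),
    ):
        try:
            rel = normalize_to_control(series, control_dose, metric=label)
        except ValueError as exc:
            warnings.warn(str(exc), stacklevel=2)
            rel = pd.Series(np.nan, index=series.index)
        groups = {
            d: transform(g["is_dead"]).to_numpy()
            for d, g in per_field.groupby("dose")
        }
        p_by_dose = _safe_dunnett(groups, control_dose, seed, report, label)
        for dose in doses:
            p = p_by_dose.get(dose, float("nan"))
            rows.append(
                dict(
                    dose=dose, metric=label, n_cells=int(n_cells[dose]),
                    mean=float(series[dose]), sd=float("nan"),
                    relative_pct=float(rel[dose]),
                    p_value=p, stars="" if np.isnan(p) else star_label(p),
                )
            )

    summary = pd.DataFrame(rows)
    return summary, report


def _dunnett_on_field_means(cells, col, control_dose, seed, report, label):
    per_field = cells.groupby(["dose", "field_id"])[col].mean().reset_index()
    groups = {d: g[col].to_numpy() for d, g in per_field.groupby("dose")}
    return _safe_dunnett(groups, control_dose, seed, report, label)


def _safe_dunnett(groups, control_dose, seed, report, label):
    try:
        res = anova_dunnett(groups, control_dose, seed=seed)
    except ValueError as exc:
        warnings.warn(f"{label}: {exc}; p-values set to NaN", stacklevel=3)
        report["metrics"][label] = {"error": str(exc)}
        return {}
    report["metrics"][label] = {
        "anova_F": res.f_statistic,
        "anova_p": res.anova_p,
        "dunnett": {str(d): res.p_for(d) for d in res.doses},
    }
    out = {d: res.p_for(d) for d in res.doses}
    out[control_dose] = float("nan")
    return out
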