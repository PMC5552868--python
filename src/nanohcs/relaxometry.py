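"""MRI relaxometry: relaxivity fitting, unit conversion and ROI normalization.

For a superparamagnetic contrast agent the observed relaxation rate
R = 1/T (longitudinal R1 = 1/T1 or transverse R2 = 1/T2) is linear in iron
concentration: R(C) = R0 + r·C, where the slope r is the relaxivity
(mM⁻¹ s⁻¹) and the intercept R0 the native rate of the solvent. A large
r2/r1 ratio marks a T2-weighted (negative-contrast) agent.

Concentrations given in µg Fe/ml convert to millimolar through the molar
mass of iron, 55.845 g/mol. Relaxation-time estimation from raw echo trains
is out of scope — inputs are the T1/T2 values scanners report.

ROI analysis for in-vivo-style longitudinal data divides each target-ROI
mean by a same-image reference ROI (muscle), then aggregates per group and
timepoint and tests treated timepoints against the pre-injection baseline
with Dunnett's many-to-one procedure.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from nanohcs.dose_stats import anova_dunnett, star_label
from nanohcs.linfit import LinearFit

IRON_MOLAR_MASS = 55.845  # g/mol


def rates_from_times(times_s) -> np.ndarray:
    """Element-wise relaxation rates R = 1/T (s⁻¹)."""
    t = np.asarray(times_s, dtype=float)
    if (t <= 0).any():
        raise ValueError("relaxation times must be positive")
    return 1.0 / t


def conc_to_mM(conc_ug_ml) -> np.ndarray | float:
    """µg Fe/ml → mM via the molar mass of iron (55.845 g/mol)."""
    c = np.asarray(conc_ug_ml, dtype=float)
    if (c < 0).any():
        raise ValueError("concentrations must be non-negative")
    out = c / IRON_MOLAR_MASS
    return float(out) if out.ndim == 0 else out


def fit_relaxivity(conc_mM, rates_s) -> LinearFit:
    """OLS fit of rate vs concentration; slope = relaxivity, intercept = R0."""
    conc_mM = np.asarray(conc_mM, dtype=float)
    rates_s = np.asarray(rates_s, dtype=float)
    if np.unique(conc_mM).size < 3:
        raise ValueError("relaxivity fit needs at least 3 distinct concentrations")
    if conc_mM.min() > 0.2 * conc_mM.max():
        warnings.warn(
            "no low/zero concentration anchor: the native-rate intercept is "
            "an extrapolation",
            stacklevel=2,
        )
    return LinearFit.fit(conc_mM, rates_s)


def relaxivity_ratio(r2: float, r1: float) -> float:
    """r2/r1; values ≫ 1 indicate a T2-weighted contrast agent."""
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    return r2 / r1


def normalize_roi(
    table: pd.DataFrame,
    baseline_timepoint: str = "pre",
    control_group: str = "control",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Reference-normalized ROI signal per group and timepoint.

    ``table`` columns: ``subject``, ``group``, ``timepoint``, ``roi_mean``,
    ``reference_mean``. Rows with a missing or non-positive reference are
    dropped with a warning. Returns a summary (group × timepoint: n, mean,
    SD of ``roi_mean/reference_mean``, percent change vs the group's
    baseline) and a stats dict with Dunnett comparisons of each
    post-baseline timepoint against baseline within each group.
    """
    required = {"subject", "group", "timepoint", "roi_mean", "reference_mean"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ROI table missing columns {sorted(missing)}")
    table = table.copy()
    bad = ~(table["reference_mean"] > 0)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} row(s) with missing/non-positive "
                      "reference ROI", stacklevel=2)
        table = table[~bad]
    if table.empty:
        raise ValueError("no usable ROI rows")
    table["normalized"] = table["roi_mean"] / table["reference_mean"]

    rows = []
    stats_report: dict = {}
    for group, g in table.groupby("group"):
        per_tp = g.groupby("timepoint")["normalized"]
        means, sds, ns = per_tp.mean(), per_tp.std(ddof=1), per_tp.size()
        base = means.get(baseline_timepoint, np.nan)
        # many-to-one test of each timepoint against the baseline timepoint
        groups = {0.0: g.loc[g["timepoint"] == baseline_timepoint, "normalized"].to_numpy()}
        tps = [t for t in means.index if t != baseline_timepoint]
        for i, tp in enumerate(tps, start=1):
            groups[float(i)] = g.loc[g["timepoint"] == tp, "normalized"].to_numpy()
        p_by_tp: dict[str, float] = {}
        if all(v.size >= 2 for v in groups.values()) and len(groups) >= 2:
            res = anova_dunnett(groups, control_dose=0.0, seed=seed)
            p_by_tp = {tp: res.p_for(float(i)) for i, tp in enumerate(tps, start=1)}
            stats_report[group] = {
                "anova_F": res.f_statistic,
                "anova_p": res.anova_p,
                "dunnett_vs_baseline": p_by_tp,
            }
        else:
            warnings.warn(f"group {group!r}: not enough subjects per timepoint "
                          "for inference", stacklevel=2)
            stats_report[group] = {"error": "insufficient replicates"}
        for tp in means.index:
            p = p_by_tp.get(tp, float("nan"))
            rows.append(
                dict(
                    group=group, timepoint=tp, n=int(ns[tp]),
                    normalized_mean=float(means[tp]),
                    normalized_sd=float(sds[tp]),
                    pct_change_vs_baseline=float(100.0 * (means[tp] - base) / base)
                    if base and not np.isnan(base) else float("nan"),
                    p_vs_baseline=p,
                    stars="" if np.isnan(p) else star_label(p),
                )
            )
    summary = pd.DataFrame(rows)
    return summary, {"baseline_timepoint": baseline_timepoint,
                     "control_group": control_group, "groups": stats_report}
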