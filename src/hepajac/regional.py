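"""Regional dose / volume-change statistics.

Per case, the EQD2 and volume-change maps are averaged over the whole liver
and its sub-regions (caudate-like segment 1, left-lobe segments 2-4, their
union the left lobe, and the merged right lobe).  The resulting per-case,
per-region rows drive all cohort statistics: Pearson correlation and
ordinary-least-squares regression of mean volume change (in percent) on
mean EQD2, stratified hypertrophy/atrophy frequency tables, and binary
event labels for ROC analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .grids import Grid3D, LabelGrid

__all__ = [
    "REGIONS",
    "RegionRegression",
    "regional_means",
    "cohort_regression",
    "change_distribution_table",
    "classify_events",
]

logger = logging.getLogger(__name__)

REGIONS = ("whole_liver", "seg1", "seg2", "seg3", "seg4", "right_lobe", "left_lobe")


@dataclass(frozen=True)
class RegionRegression:
    """Cohort-level linear fit dv% = slope * EQD2 + intercept for one region."""

    region: str
    pearson_r: float
    slope: float  # percent per Gy
    intercept: float  # percent
    n: int
    slope_stderr: float = float("nan")


def regional_means(
    dv_map: Grid3D,
    eqd2_map: Grid3D,
    labels: LabelGrid,
    case_id: str = "",
    t_days: float = float("nan"),
) -> pd.DataFrame:
    """Mean EQD2 (Gy) and mean volume change (percent) per region.

    Dose and volume change are averaged over identical voxel sets.  Empty
    regions are omitted with a warning.  Columns: case_id, region,
    mean_eqd2, mean_dv_pct, n_voxels, t_days.
    """
    if dv_map.shape != labels.shape or eqd2_map.shape != labels.shape:
        raise ValueError("dv/eqd2 maps must share the label geometry")
    dv = np.asarray(dv_map.values, dtype=float)
    dose = np.asarray(eqd2_map.values, dtype=float)
    rows = []
    for region in REGIONS:
        mask = labels.region_mask(region)
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"region {region!r} is empty for case {case_id!r}; row omitted")
            continue
        rows.append(
            {
                "case_id": case_id,
                "region": region,
                "mean_eqd2": float(dose[mask].mean()),
                "mean_dv_pct": float(dv[mask].mean()) * 100.0,
                "n_voxels": n,
                "t_days": float(t_days),
            }
        )
    return pd.DataFrame(rows)


def cohort_regression(rows: pd.DataFrame, region: str) -> RegionRegression:
    """Pearson r and OLS fit of mean dv% on mean EQD2 across cases.

    The slope standard error is heteroscedasticity-robust (HC3): patient
    sensitivity acts multiplicatively on the dose response, so residual
    variance grows with dose and the classical homoscedastic error would
    understate the slope's sampling variability.
    """
    sub = rows[rows["region"] == region]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 cases for region {region!r}, got {len(sub)}")
    x = sub["mean_eqd2"].to_numpy(dtype=float)
    y = sub["mean_dv_pct"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"zero variance in region {region!r}")
    fit = stats.linregress(x, y)
    robust = sm.OLS(y, sm.add_constant(x)).fit(cov_type="HC3")
    return RegionRegression(
        region=region,
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(sub),
        slope_stderr=float(robust.bse[1]),
    )


def change_distribution_table(
    rows: pd.DataFrame,
    region: str,
    eqd2_split_gy: float = 50.0,
    dv_thresholds: tuple[float, ...] = (0.0, 10.0),
) -> pd.DataFrame:
    """Stratified volume-change frequency table for one region.

    Among cases with mean EQD2 below the split: percentage with dv above
    each (positive) threshold, i.e. hypertrophy frequencies.  Among cases
    at or above the split: percentage with dv below each negated
    threshold, i.e. atrophy frequencies.  Strata with no cases yield NaN
    cells.
    """
    sub = rows[rows["region"] == region]
    low = sub[sub["mean_eqd2"] < eqd2_split_gy]
    high = sub[sub["mean_eqd2"] >= eqd2_split_gy]
    out = []
    for thr in dv_thresholds:
        row = {"region": region, "dv_threshold_pct": thr}
        row["pct_low_dose_dv_above"] = (
            float((low["mean_dv_pct"] > thr).mean() * 100.0) if len(low) else float("nan")
        )
        row["pct_high_dose_dv_below"] = (
            float((high["mean_dv_pct"] < -thr).mean() * 100.0) if len(high) else float("nan")
        )
        row["n_low"] = len(low)
        row["n_high"] = len(high)
        out.append(row)
    return pd.DataFrame(out)


def classify_events(
    rows: pd.DataFrame, event: str, dv_cut_pct: float = 5.0
) -> np.ndarray:
    """Binary event labels per row.

    ``hypertrophy``: dv strictly above +dv_cut_pct; ``atrophy``: dv strictly
    below -dv_cut_pct.  The atrophy cut is read as a *negative* threshold:
    a symmetric hypertrophy/atrophy dichotomy at +-5 % is the only reading
    under which the two events are disjoint and rare outcomes.
    """
    if event not in ("hypertrophy", "atrophy"):
        raise ValueError("event must be 'hypertrophy' or 'atrophy'")
    dv = rows["mean_dv_pct"].to_numpy(dtype=float)
    if event == "hypertrophy":
        return (dv > dv_cut_pct).astype(int)
    return (dv < -dv_cut_pct).astype(int)
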