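"""Evaluation battery for predicted volume-change maps.

Compares, per case, the voxel-wise Pearson correlation of a predicted map
with the registration-based map against the dose-only baseline (the negated
correlation between EQD2 and the registration-based map, so both
distributions are oriented positively).  Distribution normality is checked
with Shapiro-Wilk; the paired difference in means with a two-sided Wilcoxon
signed-rank test.  Regional agreement is summarised by Pearson r and an
identity-line coefficient of determination, and hypertrophy/atrophy
classification by ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .grids import Grid3D

__all__ = [
    "PairedCorrelations",
    "voxelwise_pearson",
    "paired_comparison",
    "regional_agreement",
    "roc_auc",
]


def voxelwise_pearson(
    map_a: Grid3D | np.ndarray, map_b: Grid3D | np.ndarray, mask: np.ndarray
) -> float:
    """Pearson r between two maps over the mask voxels only.

    Restricting to the liver mask matters: outside voxels are identically
    zero in both maps by convention and would artificially inflate r.
    """
    a = map_a.values if isinstance(map_a, Grid3D) else np.asarray(map_a)
    b = map_b.values if isinstance(map_b, Grid3D) else np.asarray(map_b)
    mask = np.asarray(mask, bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("maps and mask must share one geometry")
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"need >= 10 mask voxels, got {n}")
    av, bv = a[mask].astype(float), b[mask].astype(float)
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("zero variance inside mask; correlation undefined")
    return float(stats.pearsonr(av, bv).statistic)


@dataclass
class PairedCorrelations:
    """Paired per-case correlations of predictions and dose baseline."""

    r_pred: np.ndarray
    r_dose_opposite: np.ndarray
    mean_pred: float = field(init=False)
    sd_pred: float = field(init=False)
    mean_dose: float = field(init=False)
    sd_dose: float = field(init=False)
    shapiro_pred: tuple[float, float] = field(init=False)
    shapiro_dose: tuple[float, float] = field(init=False)
    wilcoxon_p: float = field(init=False)
    n_zero_diffs: int = field(init=False)

    def __post_init__(self) -> None:
        rp = np.asarray(self.r_pred, dtype=float)
        rd = np.asarray(self.r_dose_opposite, dtype=float)
        if rp.shape != rd.shape or rp.ndim != 1:
            raise ValueError("paired correlation lists must be 1D and equal length")
        if len(rp) < 5:
            raise ValueError("need >= 5 paired cases")
        self.r_pred, self.r_dose_opposite = rp, rd
        self.mean_pred, self.sd_pred = float(rp.mean()), float(rp.std(ddof=1))
        self.mean_dose, self.sd_dose = float(rd.mean()), float(rd.std(ddof=1))
        sw_p = stats.shapiro(rp)
        sw_d = stats.shapiro(rd)
        self.shapiro_pred = (float(sw_p.statistic), float(sw_p.pvalue))
        self.shapiro_dose = (float(sw_d.statistic), float(sw_d.pvalue))
        diffs = rp - rd
        self.n_zero_diffs = int(np.count_nonzero(diffs == 0))
        nonzero = diffs[diffs != 0]
        if nonzero.size == 0:
            # degenerate: every pair identical
            self.wilcoxon_p = 1.0
        else:
            method = "exact" if len(nonzero) <= 25 and np.unique(np.abs(nonzero)).size == nonzero.size else "approx"
            res = stats.wilcoxon(nonzero, alternative="two-sided", method=method)
            self.wilcoxon_p = float(res.pvalue)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distribution": ["predicted_vs_dir", "dose_vs_dir_opposite"],
                "mean_r": [self.mean_pred, self.mean_dose],
                "sd_r": [self.sd_pred, self.sd_dose],
                "shapiro_W": [self.shapiro_pred[0], self.shapiro_dose[0]],
                "shapiro_p": [self.shapiro_pred[1], self.shapiro_dose[1]],
                "wilcoxon_p": [self.wilcoxon_p] * 2,
            }
        )


def paired_comparison(r_pred, r_dose) -> PairedCorrelations:
    """Build the paired-comparison summary from per-case correlation lists."""
    return PairedCorrelations(np.asarray(r_pred, float), np.asarray(r_dose, float))


def regional_agreement(
    pred_rows: pd.DataFrame, truth_rows: pd.DataFrame
) -> pd.DataFrame:
    """Per-region Pearson r and identity-line R^2 of mean volume changes.

    R^2 is computed about the identity line, 1 - sum((pred-truth)^2) /
    sum((truth-mean(truth))^2): systematic under-estimation lowers R^2
    while leaving r high, separating calibration from ranking.  The
    regression-line R^2 (r squared) is reported alongside.
    """
    merged = pred_rows.merge(
        truth_rows, on=["case_id", "region"], suffixes=("_pred", "_truth")
    )
    out = []
    for region, grp in merged.groupby("region", sort=False):
        if len(grp) < 3:
            raise ValueError(f"need >= 3 matched pairs for region {region!r}")
        p = grp["mean_dv_pct_pred"].to_numpy(float)
        t = grp["mean_dv_pct_truth"].to_numpy(float)
        ss_tot = float(((t - t.mean()) ** 2).sum())
        ss_res = float(((p - t) ** 2).sum())
        r2_identity = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        if np.ptp(p) == 0 or np.ptp(t) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(p, t).statistic)
        out.append(
            {
                "region": region,
                "pearson_r": r,
                "r2_identity": r2_identity,
                "r2_regression": r**2 if np.isfinite(r) else float("nan"),
                "n": len(grp),
            }
        )
    return pd.DataFrame(out)


def roc_auc(scores, labels) -> float:
    """ROC area under the curve: P(score_pos > score_neg) + 1/2 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present for ROC AUC")
    return float(roc_auc_score(labels, scores))
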