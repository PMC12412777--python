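"""Dosimetric evaluation: DVHs, Dx% metrics, homogeneity, percent errors, and
paired model comparison.

Conventions (documented because planning systems differ):

* ``Dx%`` is the minimum dose received by the hottest x% of a structure's
  volume, computed from sorted voxel doses as the (1 - x/100) quantile with
  linear interpolation between adjacent order statistics.
* ``Dmax`` is the maximum voxel dose in the structure (no volume qualifier).
* Homogeneity index = (D2% - D98%) / D50%; zero for a perfectly uniform dose.
* Percent errors are absolute and normalized by the patient's highest
  prescription: |D_gt - D_pred| / D_rx_max * 100.
* Model comparison uses the two-tailed Wilcoxon signed-rank test at
  alpha = 0.05, with zero differences dropped and ties mid-ranked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_DVH_BINS = 1000
DX_LEVELS = (99.0, 98.0, 95.0, 50.0, 2.0)


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram for one structure."""

    dose_grid: np.ndarray  # ascending Gy
    volume_fraction: np.ndarray  # fraction of volume receiving >= dose
    structure_name: str
    voxel_count: int

    def dose_at_volume(self, x: float) -> float:
        """Dx% read off the curve by inverse interpolation."""
        if not 0 < x <= 100:
            raise ValueError("volume percentage must be in (0, 100]")
        frac = x / 100.0
        # definition-based inversion of the step curve: the largest grid dose
        # at which at least x% of the volume still receives >= that dose
        hits = np.flatnonzero(self.volume_fraction >= frac)
        if hits.size == 0:
            return float(self.dose_grid[0])
        return float(self.dose_grid[hits[-1]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_Gy": self.dose_grid, "volume_fraction": self.volume_fraction}
        )


def dvh(dose: np.ndarray, mask: np.ndarray, n_bins: int = DEFAULT_DVH_BINS,
        structure_name: str = "") -> DVHCurve:
    """Cumulative DVH over the masked voxels on a uniform grid from 0 to max."""
    if dose.shape != mask.shape:
        raise ValueError("dose and mask must share one grid")
    sel = mask > 0
    if not sel.any():
        raise ValueError("mask is empty")
    d = np.asarray(dose, dtype=np.float64)[sel]
    dmax = float(d.max())
    top = dmax if dmax > 0 else 1.0
    grid = np.linspace(0.0, top, n_bins)
    # final point just above the maximum so the curve closes at zero
    grid = np.append(grid, np.nextafter(top, np.inf))
    sorted_d = np.sort(d)
    frac = 1.0 - np.searchsorted(sorted_d, grid, side="left") / d.size
    return DVHCurve(
        dose_grid=grid,
        volume_fraction=frac,
        structure_name=structure_name,
        voxel_count=int(d.size),
    )


def dose_at_volume(doses_or_curve, x: float) -> float:
    """Dx%: minimum dose to the hottest x% of the structure volume (Gy).

    Accepts either a :class:`DVHCurve` or the structure's voxel doses.
    """
    if isinstance(doses_or_curve, DVHCurve):
        return doses_or_curve.dose_at_volume(x)
    if not 0 < x <= 100:
        raise ValueError("volume percentage must be in (0, 100]")
    d = np.asarray(doses_or_curve, dtype=np.float64).ravel()
    if d.size == 0:
        raise ValueError("no voxel doses supplied")
    return float(np.quantile(d, 1.0 - x / 100.0, method="linear"))


def homogeneity(d2: float, d98: float, d50: float) -> float:
    """(D2% - D98%) / D50%; dimensionless target-dose homogeneity index."""
    if d50 <= 0:
        raise ValueError("D50% must be positive")
    return (d2 - d98) / d50


def percent_error(gt: float, pred: float, highest_prescription: float) -> float:
    """Absolute error as a percentage of the patient's highest prescription."""
    if highest_prescription <= 0:
        raise ValueError("highest prescription must be positive")
    return abs(gt - pred) / highest_prescription * 100.0


def structure_metrics(dose: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Dmean, Dmax, Dx% family and homogeneity for one structure (Gy)."""
    sel = mask > 0
    if not sel.any():
        raise ValueError("mask is empty")
    d = np.asarray(dose, dtype=np.float64)[sel]
    out = {"Dmean": float(d.mean()), "Dmax": float(d.max())}
    for x in DX_LEVELS:
        out[f"D{x:g}%"] = dose_at_volume(d, x)
    # undefined for an unirradiated structure (D50% = 0): reported as NaN
    out["homogeneity"] = (
        homogeneity(out["D2%"], out["D98%"], out["D50%"]) if out["D50%"] > 0 else float("nan")
    )
    return out


def metrics_report(
    gt_dose: np.ndarray,
    pred_dose: np.ndarray,
    masks: dict[str, np.ndarray],
    highest_prescription: float,
) -> pd.DataFrame:
    """Per-structure ground-truth/predicted metrics and percent errors."""
    rows = []
    for name, mask in masks.items():
        if not (mask > 0).any():
            continue
        gt = structure_metrics(gt_dose, mask)
        pr = structure_metrics(pred_dose, mask)
        row = {"structure": name, "highest_prescription_Gy": highest_prescription}
        for key, val in gt.items():
            row[f"gt_{key}"] = val
            row[f"pred_{key}"] = pr[key]
            if key == "homogeneity":
                row["err_homogeneity"] = (
                    abs(val - pr[key]) if np.isfinite(val) and np.isfinite(pr[key])
                    else float("nan")
                )
            else:
                row[f"err_{key}_pct"] = percent_error(val, pr[key], highest_prescription)
        rows.append(row)
    return pd.DataFrame(rows)


def wilcoxon_signed_rank(differences: np.ndarray) -> tuple[float, bool]:
    """Two-tailed signed-rank p-value; returns (p, degenerate).

    Zero differences are dropped (standard signed-rank practice); if every
    difference is zero the comparison is degenerate and p is reported as 1.
    """
    d = np.asarray(differences, dtype=np.float64)
    d = d[d != 0]
    if d.size == 0:
        return 1.0, True
    method = "exact" if d.size <= 25 else "auto"
    try:
        res = stats.wilcoxon(d, alternative="two-sided", method=method)
    except ValueError:
        res = stats.wilcoxon(d, alternative="two-sided")
    return float(res.pvalue), False


def compare_plans(
    gt_doses: list[np.ndarray],
    pred_a: list[np.ndarray],
    pred_b: list[np.ndarray],
    masks_per_patient: list[dict[str, np.ndarray]],
    structures: list[str],
    highest_prescriptions: list[float],
    metric_names: tuple[str, ...] = ("Dmean", "Dmax"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired per-structure comparison of two models against ground truth.

    For each structure and metric: mean +/- SD of percent errors for both
    models and the Wilcoxon signed-rank p-value on the paired per-patient
    error differences.
    """
    n = len(gt_doses)
    if not (len(pred_a) == len(pred_b) == len(masks_per_patient) == n
            and len(highest_prescriptions) == n):
        raise ValueError("inputs must be paired per patient")
    rows = []
    for structure in structures:
        for metric in metric_names:
            err_a, err_b = [], []
            for gt, pa, pb, masks, rx in zip(
                gt_doses, pred_a, pred_b, masks_per_patient, highest_prescriptions
            ):
                mask = masks.get(structure)
                if mask is None or not (mask > 0).any():
                    continue
                mg = structure_metrics(gt, mask)[metric]
                err_a.append(percent_error(mg, structure_metrics(pa, mask)[metric], rx))
                err_b.append(percent_error(mg, structure_metrics(pb, mask)[metric], rx))
            err_a, err_b = np.asarray(err_a), np.asarray(err_b)
            if err_a.size == 0:
                continue
            p, degenerate = wilcoxon_signed_rank(err_a - err_b)
            rows.append(
                {
                    "structure": structure,
                    "metric": metric,
                    "n_pairs": int(err_a.size),
                    "mean_err_a_pct": float(err_a.mean()),
                    "sd_err_a_pct": float(err_a.std(ddof=1)) if err_a.size > 1 else 0.0,
                    "mean_err_b_pct": float(err_b.mean()),
                    "sd_err_b_pct": float(err_b.std(ddof=1)) if err_b.size > 1 else 0.0,
                    "p_value": p,
                    "significant": bool(p < alpha) and not degenerate,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)
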