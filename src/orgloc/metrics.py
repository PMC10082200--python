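"""Segmentation quality metrics: confusion counts, F1/TPR/PPV, VOE, RVD,
and symmetric surface distances (ASSD/MSSD).

F1 = 2TP/(2TP+FP+FN) x 100 (the Dice coefficient as a percent);
VOE = (1 - Jaccard) x 100; RVD = (|pred| - |ref|)/|ref| x 100.  TPR and
PPV default to the standard sensitivity TP/(TP+FN) and precision
TP/(TP+FP); the source formulas TPR=TP/(TP+FP), PPV=TN/(TN+FP) — which
conflict with their own names — are available behind ``paper_formulas``.

Surface voxels are mask voxels with at least one non-mask face neighbor
(6-neighborhood in 3D, 4 in 2D); distances are Euclidean, scaled by the
voxel spacing, and symmetrized over both directed distance sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "MetricsReport",
    "f1_from_counts",
    "overlap_metrics",
    "surface_metrics",
    "compute_report",
    "evaluate_cohort",
]


def f1_from_counts(tp: float, fp: float, fn: float) -> float:
    """F1 percent from (possibly averaged, hence fractional) counts."""
    return 200.0 * tp / (2.0 * tp + fp + fn)


@dataclass
class MetricsReport:
    TP: int
    FP: int
    FN: int
    TN: int
    F1: float  # percent
    TPR: float  # percent
    PPV: float  # percent
    VOE: float  # percent
    RVD: float  # percent
    ASSD: float = float("nan")  # mm
    MSSD: float = float("nan")  # mm

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("TP", "FP", "FN", "TN", "TPR", "PPV", "F1", "VOE", "RVD", "ASSD", "MSSD")}


def _check_pair(pred, ref) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(getattr(pred, "data", pred), dtype=bool)
    ref = np.asarray(getattr(ref, "data", ref), dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    return pred, ref


def overlap_metrics(pred, ref, paper_formulas: bool = False) -> MetricsReport:
    """Voxel-overlap metrics for one prediction/reference mask pair."""
    pred, ref = _check_pair(pred, ref)
    tp = int((pred & ref).sum())
    fp = int((pred & ~ref).sum())
    fn = int((~pred & ref).sum())
    tn = int((~pred & ~ref).sum())
    n_ref = tp + fn
    if n_ref == 0:
        raise ValueError("reference mask is empty; RVD undefined")
    union = tp + fp + fn
    f1 = 200.0 * tp / (2 * tp + fp + fn) if union else 100.0
    voe = (1.0 - (tp / union if union else 1.0)) * 100.0
    rvd = ((tp + fp) - n_ref) / n_ref * 100.0
    if paper_formulas:
        tpr = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        ppv = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    else:
        tpr = 100.0 * tp / (tp + fn)
        ppv = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    return MetricsReport(TP=tp, FP=fp, FN=fn, TN=tn, F1=f1, TPR=tpr, PPV=ppv, VOE=voe, RVD=rvd)


def _surface(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one non-mask face neighbor (border counts)."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def surface_metrics(pred, ref, spacing=None) -> tuple[float, float]:
    """(ASSD, MSSD) in mm between the two masks' surface voxel sets."""
    pred, ref = _check_pair(pred, ref)
    if not pred.any() or not ref.any():
        raise ValueError("surface distances undefined for an empty mask")
    if spacing is None:
        spacing = (1.0,) * pred.ndim
    sp = _surface(pred)
    sr = _surface(ref)
    d_to_ref = ndimage.distance_transform_edt(~sr, sampling=spacing)[sp]
    d_to_pred = ndimage.distance_transform_edt(~sp, sampling=spacing)[sr]
    both = np.concatenate([d_to_ref, d_to_pred])
    return float(both.mean()), float(both.max())


def compute_report(pred, ref, spacing=None, paper_formulas: bool = False) -> MetricsReport:
    """Overlap plus surface metrics in one report."""
    report = overlap_metrics(pred, ref, paper_formulas=paper_formulas)
    p, r = _check_pair(pred, ref)
    if p.any() and r.any():
        report.ASSD, report.MSSD = surface_metrics(p, r, spacing=spacing)
    return report


def evaluate_cohort(cases, spacing=None, paper_formulas: bool = False) -> pd.DataFrame:
    """Per-case metric table with an arithmetic-mean row appended.

    ``cases`` is a sequence of (pred, ref) mask pairs.  Metrics are
    computed per case and then averaged (mean of per-case ratios, not the
    ratio of summed counts).
    """
    if len(cases) == 0:
        raise ValueError("evaluate_cohort requires at least one case")
    rows = []
    for i, (pred, ref) in enumerate(cases):
        report = compute_report(pred, ref, spacing=spacing, paper_formulas=paper_formulas)
        rows.append({"Group": str(i + 1), **report.as_dict()})
    df = pd.DataFrame(rows)
    mean_row = {"Group": "mean", **df.drop(columns="Group").mean().to_dict()}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
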