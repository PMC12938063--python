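"""Segmentation-quality metrics between predicted and ground-truth masks.

Pixel-overlap metrics (accuracy, sensitivity, precision, specificity, Dice,
IoU, Matthews correlation) from the confusion counts, plus the 95th
percentile Hausdorff boundary distance in millimetres.  Stacks are scored
per slice and aggregated as mean +/- SD, matching a 2-D segmentation model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as _ndi
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class SegReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    dsc: float
    iou: float
    mcc: float
    hd95: float = float("nan")  # mm; filled when boundaries exist

    def as_dict(self) -> dict:
        return asdict(self)


def _check_binary_pair(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for name, m in (("pred", pred), ("truth", truth)):
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{name} mask is not binary")
    return pred.astype(bool), truth.astype(bool)


def confusion(pred, truth) -> tuple[int, int, int, int]:
    """Per-pixel confusion counts (TP, FP, FN, TN)."""
    p, t = _check_binary_pair(pred, truth)
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return tp, fp, fn, tn


def _safe_div(num, den, degenerate=1.0):
    return num / den if den > 0 else degenerate


def overlap_metrics(counts: tuple[int, int, int, int]) -> SegReport:
    """Derive the overlap metrics from confusion counts.

    Degenerate-denominator policy: a ratio whose reference class is absent
    scores 1 when the prediction agrees it is absent (e.g. Dice of two empty
    masks) and 0 otherwise.
    """
    tp, fp, fn, tn = counts
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty masks")
    dsc = _safe_div(2 * tp, 2 * tp + fp + fn, degenerate=1.0)
    iou = _safe_div(tp, tp + fp + fn, degenerate=1.0)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else 0.0
    return SegReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / n,
        sensitivity=_safe_div(tp, tp + fn),
        precision=_safe_div(tp, tp + fp),
        specificity=_safe_div(tn, tn + fp),
        dsc=dsc,
        iou=iou,
        mcc=mcc,
    )


def dice(pred, truth) -> float:
    tp, fp, fn, _ = confusion(pred, truth)
    return _safe_div(2 * tp, 2 * tp + fp + fn, degenerate=1.0)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (row, col) of foreground pixels with a background
    4-neighbour (inner boundary)."""
    m = np.asarray(mask).astype(bool)
    eroded = _ndi.binary_erosion(m, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]), border_value=0)
    return np.argwhere(m & ~eroded)


def hausdorff95(pred, truth, pixel_size=1.0) -> float:
    """Symmetric 95th-percentile Hausdorff boundary distance, in mm.

    The 95th percentile of the *pooled* directed boundary-to-boundary
    distances (both directions).  ``pixel_size`` may be a scalar or a
    per-axis (row, col) pair for anisotropic grids.
    """
    p, t = _check_binary_pair(pred, truth)
    if not p.any() or not t.any():
        raise ValueError("hausdorff95 requires two non-empty masks")
    scale = np.broadcast_to(np.asarray(pixel_size, dtype=float), (2,))
    bp = boundary_pixels(p) * scale
    bt = boundary_pixels(t) * scale
    d_pt = cKDTree(bt).query(bp)[0]
    d_tp = cKDTree(bp).query(bt)[0]
    pooled = np.concatenate([d_pt, d_tp])
    return float(np.percentile(pooled, 95, method="linear"))


def evaluate_pair(pred, truth, pixel_size=1.0) -> SegReport:
    """Full per-slice report: overlap metrics plus HD95 (mm)."""
    counts = confusion(pred, truth)
    report = overlap_metrics(counts)
    p, t = np.asarray(pred).astype(bool), np.asarray(truth).astype(bool)
    if p.any() and t.any():
        hd = hausdorff95(pred, truth, pixel_size)
    elif not p.any() and not t.any():
        hd = 0.0
    else:
        hd = float("nan")
    return SegReport(**{**report.as_dict(), "hd95": hd})


def evaluate_stack(pred_stack, truth_stack, pixel_size=1.0):
    """Score a stack slice-by-slice; returns (list of SegReport, aggregate
    dict of mean and SD per metric)."""
    pred_stack = np.asarray(pred_stack)
    truth_stack = np.asarray(truth_stack)
    if pred_stack.shape != truth_stack.shape:
        raise ValueError("stack shape mismatch")
    reports = [evaluate_pair(p, t, pixel_size)
               for p, t in zip(pred_stack, truth_stack)]
    keys = ["accuracy", "sensitivity", "precision", "specificity",
            "dsc", "iou", "mcc", "hd95"]
    aggregate = {}
    for k in keys:
        vals = np.array([getattr(r, k) for r in reports], dtype=float)
        vals = vals[~np.isnan(vals)]
        aggregate[k] = {"mean": float(vals.mean()) if len(vals) else
                        float("nan"),
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1
                        else 0.0}
    return reports, aggregate
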