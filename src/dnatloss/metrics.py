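"""Segmentation evaluation metrics.

Seven metrics: Dice, IoU, false discovery rate (FDR), Hausdorff distance
(HD), average symmetric surface distance (ASSD), expected calibration
error (ECE) and mutual information (MI, bits).  Conventions:

* boundaries are foreground pixels with at least one background
  4-neighbour, the image border counting as background; distances are
  Euclidean between pixel centres;
* HD/ASSD on an empty boundary return the image diagonal and set a flag
  rather than failing silently;
* ECE uses 10 uniform bins over confidence max(p, 1−p) and is pooled
  over all test pixels, while every other metric is averaged per image;
* MI is computed on the empirical 2×2 joint of (predicted, true) labels
  with base-2 logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


# -- overlap metrics ---------------------------------------------------------

def confusion_counts(pred, gt) -> tuple[int, int, int, int]:
    p = np.asarray(pred).astype(bool)
    g = np.asarray(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return tp, fp, fn, tn


def dice(pred, gt) -> float:
    tp, fp, fn, _ = confusion_counts(pred, gt)
    if tp + fp + fn == 0:
        return 1.0  # both empty: perfect agreement
    return 2.0 * tp / (2.0 * tp + fp + fn)


def iou(pred, gt) -> float:
    tp, fp, fn, _ = confusion_counts(pred, gt)
    if tp + fp + fn == 0:
        return 1.0
    return tp / (tp + fp + fn)


def fdr(pred, gt) -> float:
    tp, fp, _, _ = confusion_counts(pred, gt)
    if tp + fp == 0:
        return 0.0  # no discoveries, no false discoveries
    return fp / (tp + fp)


# -- boundary metrics --------------------------------------------------------

def extract_boundary(mask) -> np.ndarray:
    """(k,2) array of boundary pixel coordinates (row, col), 0-based.

    A boundary pixel is foreground with ≥1 background 4-neighbour; the
    image border counts as background.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    padded = np.pad(m, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return np.argwhere(m & ~interior)


def _directed_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    tree = cKDTree(dst)
    d, _ = tree.query(src, k=1)
    return np.asarray(d, dtype=np.float64)


def _diagonal(shape) -> float:
    h, w = shape
    return float(np.hypot(h, w))


def hausdorff(pred, gt) -> tuple[float, bool]:
    """Symmetric Hausdorff distance in pixels; second value flags an
    empty boundary (distance then defaults to the image diagonal)."""
    p = np.asarray(pred)
    bp, bg = extract_boundary(pred), extract_boundary(gt)
    if len(bp) == 0 or len(bg) == 0:
        return _diagonal(p.shape), True
    d_pg = _directed_distances(bp, bg).max()
    d_gp = _directed_distances(bg, bp).max()
    return float(max(d_pg, d_gp)), False


def assd(pred, gt) -> tuple[float, bool]:
    """Average symmetric surface distance in pixels (+ empty-boundary flag)."""
    p = np.asarray(pred)
    bp, bg = extract_boundary(pred), extract_boundary(gt)
    if len(bp) == 0 or len(bg) == 0:
        return _diagonal(p.shape), True
    total = _directed_distances(bp, bg).sum() + _directed_distances(bg, bp).sum()
    return float(total / (len(bp) + len(bg))), False


# -- calibration and information --------------------------------------------

def ece(probs, gt, bins: int = 10) -> float:
    """Expected calibration error over pooled pixels.

    Accepts one map or a sequence of maps (pooled).  Confidence is
    max(p, 1−p); the associated prediction is p > 0.5; accuracy is its
    agreement with the label.
    """
    if isinstance(probs, (list, tuple)):
        p = np.concatenate([np.asarray(x).ravel() for x in probs])
        g = np.concatenate([np.asarray(x).ravel() for x in gt])
    else:
        p = np.asarray(probs).ravel()
        g = np.asarray(gt).ravel()
    if p.size == 0:
        raise ValueError("ece of an empty input is undefined")
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    conf = np.maximum(p, 1.0 - p)
    correct = ((p > 0.5).astype(int) == g.astype(int))
    idx = np.minimum((conf * bins).astype(int), bins - 1)
    total = p.size
    err = 0.0
    for b in range(bins):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        err += (n / total) * abs(correct[sel].mean() - conf[sel].mean())
    return float(err)


def mutual_information(pred, gt) -> float:
    """MI of the 2×2 empirical joint of (pred, gt) labels, in bits."""
    p = np.asarray(pred).astype(int).ravel()
    g = np.asarray(gt).astype(int).ravel()
    if p.shape != g.shape:
        raise ValueError("shape mismatch")
    n = p.size
    mi = 0.0
    for a in (0, 1):
        for b in (0, 1):
            joint = np.sum((p == a) & (g == b)) / n
            if joint == 0:
                continue
            marg = (np.sum(p == a) / n) * (np.sum(g == b) / n)
            mi += joint * np.log2(joint / marg)
    return float(max(mi, 0.0))


# -- dataset-level aggregation -----------------------------------------------

@dataclass
class MetricReport:
    dice: float
    iou: float
    fdr: float
    hd_px: float
    assd_px: float
    ece: float
    mi_bits: float
    per_image: bool = False
    n_images: int = 1
    empty_boundary_images: int = 0
    per_image_table: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("dice", "iou", "fdr", "hd_px", "assd_px", "ece", "mi_bits",
                 "n_images", "empty_boundary_images")}


def evaluate_image(probs, pred, gt) -> dict:
    hd_val, hd_flag = hausdorff(pred, gt)
    assd_val, assd_flag = assd(pred, gt)
    return {
        "dice": dice(pred, gt),
        "iou": iou(pred, gt),
        "fdr": fdr(pred, gt),
        "hd_px": hd_val,
        "assd_px": assd_val,
        "ece": ece(probs, gt),
        "mi_bits": mutual_information(pred, gt),
        "empty_boundary": bool(hd_flag or assd_flag),
    }


def evaluate_dataset(pairs) -> MetricReport:
    """pairs: iterable of (probs, pred, gt).

    Per-image metrics are unweighted means; ECE is recomputed once over
    the pooled pixels of the whole set.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_dataset requires at least one image")
    rows = [evaluate_image(p, m, g) for p, m, g in pairs]
    table = pd.DataFrame(rows)
    pooled_ece = ece([p for p, _, _ in pairs], [g for _, _, g in pairs])
    return MetricReport(
        dice=float(table["dice"].mean()),
        iou=float(table["iou"].mean()),
        fdr=float(table["fdr"].mean()),
        hd_px=float(table["hd_px"].mean()),
        assd_px=float(table["assd_px"].mean()),
        ece=pooled_ece,
        mi_bits=float(table["mi_bits"].mean()),
        per_image=False,
        n_images=len(pairs),
        empty_boundary_images=int(table["empty_boundary"].sum()),
        per_image_table=table,
    )
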