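"""Segmentation evaluation: Jaccard coefficient against ground truth.

The Jaccard coefficient JC = |A ∩ B| / |A ∪ B| compares a segmentation
mask with a reference mask; per-frame values are aggregated to a mean and
a sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath

from .snake import Contour, ContourError

__all__ = ["contour_to_mask", "jaccard", "hausdorff", "evaluate_run", "EvalStats"]


def contour_to_mask(contour, shape) -> np.ndarray:
    """Rasterize a closed contour: a pixel is foreground iff its center
    (integer (x, y) coordinate) lies inside the polygon."""
    c = contour if isinstance(contour, Contour) else Contour(contour)
    if c.area <= 0:
        raise ContourError("cannot rasterize a zero-area contour")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    inside = _MplPath(c.points).contains_points(centers)
    return inside.reshape(h, w)


def jaccard(a, b) -> float:
    """Jaccard coefficient |A ∩ B| / |A ∪ B| of two same-shape binary masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise ValueError("Jaccard of two empty masks is undefined (0/0)")
    inter = int(np.logical_and(a, b).sum())
    return inter / union


def hausdorff(points_a, points_b) -> float:
    """Symmetric Hausdorff distance between two point sets (px)."""
    from scipy.spatial import cKDTree

    a = np.atleast_2d(np.asarray(points_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(points_b, dtype=np.float64))
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba))


@dataclass
class EvalStats:
    per_frame: pd.DataFrame
    mean: float
    std: float


def evaluate_run(results, truths) -> EvalStats:
    """Per-frame Jaccard of predicted masks against ground-truth masks.

    ``results`` is a TrackResult (its per-frame masks are used) or a list
    of binary masks.  The standard deviation is the sample (n-1)
    convention; a single frame reports std 0.
    """
    masks = getattr(results, "masks", results)
    masks = list(masks)
    truths = list(truths)
    if len(masks) == 0:
        raise ValueError("no masks to evaluate")
    if len(masks) != len(truths):
        raise ValueError(f"length mismatch: {len(masks)} predictions vs {len(truths)} truths")
    jcs = [jaccard(m, t) for m, t in zip(masks, truths)]
    df = pd.DataFrame({"frame": np.arange(len(jcs)), "jaccard": jcs})
    mean = float(np.mean(jcs))
    std = float(np.std(jcs, ddof=1)) if len(jcs) > 1 else 0.0
    return EvalStats(per_frame=df, mean=mean, std=std)
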