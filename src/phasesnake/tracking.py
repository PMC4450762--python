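"""Frame-to-frame segmentation-as-tracking.

The first frame is initialized by the histogram/morphology procedure; on
every frame the external force field of the (fixed) ROI is recomputed and
the snake evolves from the contour inherited unchanged from the previous
frame — inter-frame cell displacement is assumed small relative to the
force field's capture range.  If the evolution collapses mid-sequence the
frame is re-initialized from scratch once; a second failure aborts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config
from .initialization import initial_contour
from .io import RectROI, crop
from .pipeline import build_force_field
from .evaluation import contour_to_mask
from .snake import Contour, ContourCollapseError, evolve

__all__ = ["FrameRecord", "TrackResult", "track", "summarize"]

logger = logging.getLogger(__name__)


@dataclass
class FrameRecord:
    index: int
    contour: Contour          # coordinates local to this frame's ROI
    mask: np.ndarray          # ROI-shaped binary mask
    iterations: int
    converged: bool
    reinitialized: bool = False
    roi: RectROI | None = None  # this frame's ROI (differs when re-centering)


@dataclass
class TrackResult:
    frames: list[FrameRecord]
    roi: RectROI
    config: dict
    frame_interval: float | None = None  # seconds; metadata only

    @property
    def contours(self) -> list[Contour]:
        return [f.contour for f in self.frames]

    @property
    def masks(self) -> list[np.ndarray]:
        return [f.mask for f in self.frames]

    def __len__(self) -> int:
        return len(self.frames)


def track(
    frames,
    roi: RectROI,
    config: Config | None = None,
    frame_interval: float | None = None,
) -> TrackResult:
    """Track the single target cell through a frame sequence.

    ``roi`` is selected once on the first frame; by default it is reused
    for every frame (``config.recenter_roi`` re-centers it on the
    previous contour's centroid instead, for long drifts).  Returns one
    record per input frame, in order; each record's contour and mask are
    local to that frame's ROI.
    """
    frames = [np.asarray(f) for f in frames]
    if not frames:
        raise ValueError("no frames to track")
    config = config or Config()
    image_shape = frames[0].shape
    roi = RectROI(*roi).validate(image_shape)
    current_roi = roi

    contour = initial_contour(
        crop(frames[0], current_roi),
        disk_radius=config.init_disk_radius,
        threshold_tol=config.threshold_tol,
        target_spacing=config.target_spacing,
    )

    records: list[FrameRecord] = []
    params = config.snake_params
    for k, frame in enumerate(frames):
        roi_img = crop(frame, current_roi)
        fld, _ = build_force_field(roi_img, config)
        reinitialized = False
        try:
            res = evolve(contour, fld, params)
        except ContourCollapseError:
            if k == 0:
                raise
            logger.warning("frame %d: evolution collapsed; re-initializing once", k)
            reinitialized = True
            contour = initial_contour(
                roi_img,
                disk_radius=config.init_disk_radius,
                threshold_tol=config.threshold_tol,
                target_spacing=config.target_spacing,
            )
            res = evolve(contour, fld, params)  # a second collapse aborts
        contour = res.contour
        records.append(
            FrameRecord(
                index=k,
                contour=contour,
                mask=contour_to_mask(contour, roi_img.shape),
                iterations=res.iterations,
                converged=res.converged,
                reinitialized=reinitialized,
                roi=current_roi,
            )
        )
        if config.recenter_roi and k + 1 < len(frames):
            current_roi, contour = _recenter(current_roi, contour, image_shape)
    return TrackResult(
        frames=records, roi=roi, config=config.to_dict(), frame_interval=frame_interval
    )


def _recenter(roi: RectROI, contour: Contour, image_shape) -> tuple[RectROI, Contour]:
    """Shift the ROI so the contour centroid sits at its center, clamped
    to the image; the contour is re-expressed in the new ROI's frame."""
    h, w = roi.shape
    ih, iw = image_shape
    cx, cy = contour.centroid
    row0 = int(round(roi.row0 + cy - h / 2.0))
    col0 = int(round(roi.col0 + cx - w / 2.0))
    row0 = min(max(row0, 0), ih - h)
    col0 = min(max(col0, 0), iw - w)
    new_roi = RectROI(row0, col0, row0 + h, col0 + w)
    shift = np.array([roi.col0 - new_roi.col0, roi.row0 - new_roi.row0], dtype=float)
    return new_roi, Contour(contour.points + shift)


def summarize(result: TrackResult) -> pd.DataFrame:
    """Per-frame morphology table: area, perimeter, centroid, convergence.

    Columns: frame, time (when a frame interval is known), area_px2,
    perimeter_px, centroid_x, centroid_y, iterations, converged,
    reinitialized.
    """
    if not result.frames:
        raise ValueError("empty tracking result")
    rows = []
    for rec in result.frames:
        cx, cy = rec.contour.centroid
        rows.append(
            {
                "frame": rec.index,
                "area_px2": rec.contour.area,
                "perimeter_px": rec.contour.perimeter,
                "centroid_x": cx,
                "centroid_y": cy,
                "iterations": rec.iterations,
                "converged": rec.converged,
                "reinitialized": rec.reinitialized,
            }
        )
    df = pd.DataFrame(rows)
    if result.frame_interval is not None:
        df.insert(1, "time_s", df["frame"] * result.frame_interval)
    return df
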