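"""End-to-end single-frame segmentation: crop -> initialize -> force field -> snake."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Config
from .external_force import (
    VectorField,
    gvf_field,
    make_vfc_kernel,
    normalize_field,
    vfc_field,
)
from .evaluation import contour_to_mask
from .feature_map import gradient_edge_map, mgrl_feature_map
from .initialization import initial_contour
from .io import RectROI, crop
from .snake import Contour, evolve

__all__ = ["SegmentResult", "build_force_field", "segment", "segment_roi"]


@dataclass
class SegmentResult:
    contour: Contour                 # ROI-local coordinates
    mask: np.ndarray                 # ROI-shaped binary mask
    initial: Contour
    iterations: int
    converged: bool
    feature_fraction: float          # nonzero fraction of the feature map
    config: dict = field(default_factory=dict)


def build_force_field(roi_image, config: Config) -> tuple[VectorField, np.ndarray]:
    """External force field of a cropped ROI per the configured method.

    Returns ``(field, feature_map)``.  ``vfc_mgrl`` convolves the binary
    MGRL feature map with the VFC kernel; ``vfc_edge`` uses the
    traditional gradient edge map (scaled to [0, 1]) with the same kernel;
    ``gvf`` diffuses the gradient edge map.
    """
    roi_image = np.asarray(roi_image, dtype=np.float64)
    if config.force_field == "vfc_mgrl":
        fmap = mgrl_feature_map(
            roi_image,
            log_sigma=config.log_sigma,
            log_size=config.log_size,
            min_component_size=config.min_component_size,
            amplitude_eps=config.amplitude_eps,
        ).astype(np.float64)
        kernel = make_vfc_kernel(config.vfc_radius, config.vfc_r, config.vfc_eps)
        fld = vfc_field(fmap, kernel)
    elif config.force_field == "vfc_edge":
        fmap = gradient_edge_map(roi_image, config.edge_sigma)
        peak = fmap.max()
        if peak > 0:
            fmap = fmap / peak
        kernel = make_vfc_kernel(config.vfc_radius, config.vfc_r, config.vfc_eps)
        fld = vfc_field(fmap, kernel)
    else:  # gvf
        fmap = gradient_edge_map(roi_image, config.edge_sigma)
        peak = fmap.max()
        if peak > 0:
            fmap = fmap / peak
        fld = gvf_field(fmap, mu=config.gvf_mu, n_iter=config.gvf_iters)
        if config.gvf_normalize:
            # unit-magnitude GVF force is the standard practice of the
            # reference GVF snake implementation
            fld = normalize_field(fld)
    if config.normalize_force:
        fld = normalize_field(fld)
    return fld, fmap


def segment_roi(roi_image, config: Config | None = None, init: Contour | None = None) -> SegmentResult:
    """Segment a cropped ROI containing a single target cell.

    ``init`` overrides the histogram/morphology initialization (used by
    the tracking loop, which inherits the previous frame's contour).
    """
    config = config or Config()
    roi_image = np.asarray(roi_image, dtype=np.float64)
    if init is None:
        init = initial_contour(
            roi_image,
            disk_radius=config.init_disk_radius,
            threshold_tol=config.threshold_tol,
            target_spacing=config.target_spacing,
        )
    fld, fmap = build_force_field(roi_image, config)
    result = evolve(init, fld, config.snake_params)
    mask = contour_to_mask(result.contour, roi_image.shape)
    fraction = float(np.count_nonzero(fmap)) / fmap.size
    return SegmentResult(
        contour=result.contour,
        mask=mask,
        initial=init,
        iterations=result.iterations,
        converged=result.converged,
        feature_fraction=fraction,
        config=config.to_dict(),
    )


def segment(image, roi: RectROI, config: Config | None = None) -> SegmentResult:
    """Segment the target cell within a user-selected ROI of a full frame.

    The returned contour and mask are in ROI-local coordinates.
    """
    roi = RectROI(*roi)
    return segment_roi(crop(image, roi), config)
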