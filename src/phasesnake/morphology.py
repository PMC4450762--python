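"""Gray-scale and binary morphology primitives.

The central operation is morphological gray-scale reconstruction (MGR):
the limit of iterated geodesic dilation of a *marker* image under a *mask*
image.  Reconstruction-based hole filling flattens the interior of a dark
cell into a single intensity plateau — regional minima that are not
connected to the image border (the cell body and any darker inclusions
inside it) are raised to the lowest saddle on any path to the border.
Later pipeline stages exploit the plateau twice: it dominates the
intensity histogram (threshold selection) and it carries no interior
gradients (no spurious zero crossings inside the cell).

All gray-scale operations work in float64 and use 8-connectivity.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import morphology as _skmorph

__all__ = [
    "grayscale_reconstruct",
    "fill_holes",
    "remove_small_components",
    "open_close",
]

#: 3x3 structuring element: 8-connected geodesic dilation steps.
_FOOTPRINT_8 = np.ones((3, 3), dtype=bool)


def _as_float_image(image, name: str) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D single-channel image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    return arr


def grayscale_reconstruct(marker, mask) -> np.ndarray:
    """Reconstruction by dilation of ``mask`` from ``marker``.

    Iterates geodesic dilation ``marker <- min(dilate3x3(marker), mask)``
    to its fixpoint (computed by the hybrid algorithm of scikit-image,
    which is exactly that fixpoint).

    Parameters
    ----------
    marker, mask : 2-D array_like, same shape
        ``marker <= mask`` is expected everywhere.  Violations are clamped
        to the mask with a warning, since user-supplied markers may graze
        the mask by rounding.

    Returns
    -------
    ndarray of float64, ``marker <= out <= mask`` pointwise.
    """
    marker = _as_float_image(marker, "marker")
    mask = _as_float_image(mask, "mask")
    if marker.shape != mask.shape:
        raise ValueError(
            f"marker shape {marker.shape} does not match mask shape {mask.shape}"
        )
    if np.any(marker > mask):
        warnings.warn(
            "marker exceeds mask at some pixels; clamping marker to mask",
            stacklevel=2,
        )
        marker = np.minimum(marker, mask)
    return _skmorph.reconstruction(marker, mask, method="dilation", footprint=_FOOTPRINT_8)


def fill_holes(image) -> np.ndarray:
    """Fill gray-scale "holes": raise regional minima not connected to the border.

    Realized as border-seeded reconstruction on the intensity complement:
    with ``c = max(I) - I``, the marker equals ``c`` on the 1-pixel border
    and the global minimum of ``c`` elsewhere; the reconstruction of ``c``
    from that marker is complemented back.  The output never falls below
    the input and leaves border pixels unchanged; the operation is
    idempotent.
    """
    img = _as_float_image(image, "image")
    hi = float(img.max())
    comp = hi - img
    marker = np.full_like(comp, comp.min())
    marker[0, :] = comp[0, :]
    marker[-1, :] = comp[-1, :]
    marker[:, 0] = comp[:, 0]
    marker[:, -1] = comp[:, -1]
    filled = grayscale_reconstruct(marker, comp)
    return hi - filled


def remove_small_components(binary, min_size: int = 15) -> np.ndarray:
    """Remove 8-connected foreground components with fewer than ``min_size`` pixels.

    ``min_size`` defaults to 15 (low end of the recommended 15-20 range).
    Components with exactly ``min_size`` pixels or more are kept untouched.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    b = np.asarray(binary).astype(bool)
    if b.ndim != 2:
        raise ValueError(f"binary image must be 2-D, got shape {b.shape}")
    # max_size removes components <= its value, so strictly-smaller-than
    # min_size translates to max_size = min_size - 1.
    return _skmorph.remove_small_objects(b, max_size=min_size - 1, connectivity=2)


def open_close(binary, radius: int = 3) -> np.ndarray:
    """Binary opening followed by closing with a flat disk of ``radius`` pixels.

    The open-close alternating filter removes foreground specks smaller
    than the disk, then bridges comparably small gaps; it is idempotent.
    Default radius 3.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    b = np.asarray(binary).astype(bool)
    if b.ndim != 2:
        raise ValueError(f"binary image must be 2-D, got shape {b.shape}")
    se = _skmorph.disk(radius)
    return _skmorph.closing(_skmorph.opening(b, se), se).astype(bool)
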