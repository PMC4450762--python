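"""Reading image sequences and writing contours, masks, and overlays.

Sequences come either as a multi-page TIFF (frames in page order) or as a
directory of same-shape single-channel TIFF/PNG files (lexicographic
filename order).  Multi-channel frames are converted to luminance with the
ITU-R BT.601-ish weighting used by scikit-image (0.2125 R + 0.7154 G +
0.0721 B).  Contours serialize to CSV (one row per point:
frame_index, point_index, x, y) or JSON; masks to 8-bit 0/255 PNG.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import NamedTuple, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.color import rgb2gray
from skimage.draw import polygon_perimeter

from .snake import Contour

__all__ = [
    "RectROI",
    "read_sequence",
    "crop",
    "write_contours",
    "read_contours",
    "write_mask",
    "read_mask",
    "write_overlay",
]

_SUFFIXES = (".tif", ".tiff", ".png")


class RectROI(NamedTuple):
    """Half-open rectangular ROI, 0-based pixel bounds [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row1 - self.row0, self.col1 - self.col0)

    def validate(self, image_shape) -> "RectROI":
        h, w = image_shape
        if not (0 <= self.row0 < self.row1 <= h and 0 <= self.col0 < self.col1 <= w):
            raise ValueError(f"ROI {self} out of bounds for image shape {(h, w)}")
        return self

    @classmethod
    def parse(cls, text: str) -> "RectROI":
        """Parse 'row0,col0,row1,col1'."""
        parts = [int(p) for p in text.split(",")]
        if len(parts) != 4:
            raise ValueError(f"expected 'row0,col0,row1,col1', got {text!r}")
        return cls(*parts)


def _to_gray(frame: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(frame)
    if arr.ndim == 2:
        return arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        if rgb.max() > 1.0:
            rgb = rgb / 255.0
        return rgb2gray(rgb) * 255.0
    raise ValueError(f"{name}: unsupported frame shape {arr.shape}")


def read_sequence(path) -> list[np.ndarray]:
    """Read an image sequence as a list of 2-D float64 frames.

    ``path`` is a (multi-page) TIFF / PNG file or a directory of
    same-shape TIFF/PNG files.  Frames are returned in page order for a
    stack and in lexicographic filename order for a directory.  Empty
    input and shape mismatches raise, naming the offending file.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _SUFFIXES)
        if not files:
            raise ValueError(f"no TIFF/PNG files found in directory {p}")
        frames = [_to_gray(iio.imread(f), f.name) for f in files]
        shape = frames[0].shape
        for f, frame in zip(files, frames):
            if frame.shape != shape:
                raise ValueError(
                    f"frame shape mismatch: {f.name} has {frame.shape}, expected {shape}"
                )
        return frames
    if not p.exists():
        raise FileNotFoundError(p)
    if p.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(p)
    else:
        stack = iio.imread(p)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return [_to_gray(stack, p.name)]
    if stack.ndim == 3 and stack.shape[-1] in (3, 4) and stack.shape[0] not in (3, 4):
        return [_to_gray(stack, p.name)]
    frames = [_to_gray(page, f"{p.name}[{i}]") for i, page in enumerate(stack)]
    if not frames:
        raise ValueError(f"empty image stack: {p}")
    return frames


def crop(image, roi: RectROI) -> np.ndarray:
    """Crop an image to a ROI (returns a copy)."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {img.shape}")
    roi = RectROI(*roi).validate(img.shape)
    return img[roi.row0 : roi.row1, roi.col0 : roi.col1].copy()


def write_contours(contours, path, frame_indices: Sequence[int] | None = None) -> None:
    """Serialize contours to CSV (default) or JSON, chosen by suffix.

    CSV columns: frame_index, point_index, x, y with 6-decimal coordinates.
    A single Contour may be passed instead of a list.
    """
    if isinstance(contours, Contour):
        contours = [contours]
    contours = [c if isinstance(c, Contour) else Contour(c) for c in contours]
    if frame_indices is None:
        frame_indices = range(len(contours))
    p = Path(path)
    if p.suffix.lower() == ".json":
        payload = [
            {"frame_index": int(fi), "points": np.round(c.points, 6).tolist()}
            for fi, c in zip(frame_indices, contours)
        ]
        p.write_text(json.dumps(payload))
        return
    with open(p, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "point_index", "x", "y"])
        for fi, c in zip(frame_indices, contours):
            for pi, (x, y) in enumerate(c.points):
                writer.writerow([fi, pi, f"{x:.6f}", f"{y:.6f}"])


def read_contours(path) -> dict[int, Contour]:
    """Read a contour CSV/JSON back as {frame_index: Contour}."""
    p = Path(path)
    if p.suffix.lower() == ".json":
        payload = json.loads(p.read_text())
        return {int(rec["frame_index"]): Contour(rec["points"]) for rec in payload}
    frames: dict[int, list[tuple[float, float]]] = {}
    with open(p, newline="") as fh:
        for row in csv.DictReader(fh):
            frames.setdefault(int(row["frame_index"]), []).append(
                (float(row["x"]), float(row["y"]))
            )
    return {fi: Contour(pts) for fi, pts in frames.items()}


def write_mask(mask, path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground 255, background 0)."""
    m = np.asarray(mask).astype(bool)
    iio.imwrite(Path(path), (m.astype(np.uint8) * 255))


def read_mask(path) -> np.ndarray:
    """Read a mask PNG back to a boolean array (threshold at 128)."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr >= 128


def write_overlay(image, contour, path, color=(255, 40, 40)) -> None:
    """Write the frame as RGB PNG with the contour drawn on top."""
    img = np.asarray(image, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    gray = ((img - lo) * scale).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    c = contour if isinstance(contour, Contour) else Contour(contour)
    rr, cc = polygon_perimeter(
        np.round(c.points[:, 1]).astype(int),
        np.round(c.points[:, 0]).astype(int),
        shape=gray.shape,
        clip=True,
    )
    rgb[rr, cc] = color
    iio.imwrite(Path(path), rgb)
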