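"""Synthetic phase-contrast-like single-cell images with ground truth.

The generator emulates the salient structure of phase-contrast recordings
of a single lymphocyte: a dark, deformable cell body on a brighter,
noisy background; a bright "phase halo" hugging the boundary with a sharp
inner rise and a slow outer decay; intensity inhomogeneity ("holes",
darker patches) inside the body; boundary arcs of genuinely low contrast;
and distractor blobs away from the cell.  The boundary is a star-convex
curve with low-order Fourier harmonics, so the exact ground-truth mask is
known analytically and is a single 8-connected component.

Low-contrast arcs attenuate the halo amplitude by the stated factor *and*
fade the body edge toward the background over the same angular span: a
boundary arc is only low-contrast if the cell/background step itself is
weak there, not merely the halo.

Intensities are on a nominal 8-bit scale (0-255) stored as float64.
All randomness (hole placement, distractors, noise, sequence dynamics)
derives from the spec seeds, so identical specs render identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy import ndimage as ndi

__all__ = ["SceneSpec", "SequenceSpec", "make_cell_image", "make_cell_sequence", "random_scene"]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a single rendered scene.

    Geometry is in pixels, intensities on the nominal 0-255 scale.
    ``cell_center`` is (x, y) = (column, row).  ``fourier_coeffs`` holds
    (order, amplitude, phase) triples defining the boundary radius
    ``R(theta) = base_radius + sum a_k cos(k theta + phi_k)``.
    ``low_contrast_arcs`` holds (theta0, theta1, factor) spans (radians,
    counter-clockwise from theta0 to theta1) where the edge contrast is
    scaled down to ``factor`` (0.25-0.5 covers the regime of interest).
    """

    image_shape: tuple[int, int] = (256, 256)
    cell_center: tuple[float, float] = (128.0, 128.0)
    base_radius: float = 32.0
    fourier_coeffs: tuple[tuple[int, float, float], ...] = (
        (2, 2.0, 0.7),
        (3, 1.3, 2.4),
        (4, 0.8, 4.4),
    )
    body_level: float = 60.0
    background_level: float = 130.0
    halo_level: float = 200.0
    halo_width: float = 8.0          # outer skirt decay scale of the halo (px)
    halo_rise: float = 0.9           # inner rise scale of the halo (px)
    halo_peak_offset: float = 1.5    # halo crest distance outside the boundary (px)
    hole_count: int = 3
    hole_radius: float = 4.0
    hole_depth: float = 30.0
    low_contrast_arcs: tuple[tuple[float, float, float], ...] = ((0.6, 1.8, 0.35),)
    edge_fade_width: float = 3.0     # body-edge fade scale on low-contrast arcs (px)
    distractor_count: int = 2
    distractor_radius: float = 5.0
    noise_sigma: float = 1.8
    blur_sigma: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not (self.body_level < self.background_level < self.halo_level):
            raise ValueError("levels must satisfy body < background < halo")
        if self.base_radius < 8:
            raise ValueError(f"base_radius must be >= 8 px, got {self.base_radius}")
        for t0, t1, f in self.low_contrast_arcs:
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"arc contrast factor must be in [0, 1], got {f}")

    @property
    def max_radius(self) -> float:
        return self.base_radius + sum(abs(a) for _, a, _ in self.fourier_coeffs)

    @property
    def halo_extent(self) -> float:
        """Distance outside the boundary beyond which the halo is negligible."""
        return self.halo_peak_offset + 3.0 * self.halo_width

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SequenceSpec:
    """A scene plus simple temporal dynamics.

    ``drift`` is the per-frame centroid displacement (dx, dy) in px; the
    boundary harmonic amplitudes follow a seeded Gaussian random walk of
    scale ``walk_scale`` px/frame, clipped to [0, 0.12 * base_radius] so
    the deformation stays smooth and the cell stays star-convex.
    """

    base: SceneSpec = field(default_factory=SceneSpec)
    n_frames: int = 30
    drift: tuple[float, float] = (0.7, -0.5)
    walk_scale: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if np.hypot(*self.drift) > 0.3 * self.base.base_radius:
            raise ValueError("per-frame drift must stay small relative to the cell size")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _boundary_radius(spec: SceneSpec, theta: np.ndarray) -> np.ndarray:
    r = np.full_like(theta, spec.base_radius, dtype=np.float64)
    for k, amp, phase in spec.fourier_coeffs:
        r += amp * np.cos(k * theta + phase)
    return r


def _contrast_factor(spec: SceneSpec, theta: np.ndarray, taper: float = 0.25) -> np.ndarray:
    """Angular contrast profile: 1 outside low-contrast arcs, the arc factor
    inside, with a smoothstep taper of ``taper`` radians at the arc ends."""
    f = np.ones_like(theta)
    two_pi = 2.0 * np.pi
    for t0, t1, fac in spec.low_contrast_arcs:
        if abs(t1 - t0) >= two_pi - 1e-9:  # full circle: uniform, no taper
            f = np.minimum(f, fac)
            continue
        span = (t1 - t0) % two_pi
        into = (theta - t0) % two_pi
        inside = into <= span
        depth = np.minimum(into, span - into)
        s = np.clip(depth / taper, 0.0, 1.0)
        s = s * s * (3.0 - 2.0 * s)
        f = np.where(inside, np.minimum(f, 1.0 - (1.0 - fac) * s), f)
    return f


def true_boundary(spec: SceneSpec, n: int = 720) -> np.ndarray:
    """Analytic boundary polygon, (n, 2) array of (x, y) points."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = _boundary_radius(spec, theta)
    cx, cy = spec.cell_center
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def make_cell_image(spec: SceneSpec, noise_rng: np.random.Generator | None = None):
    """Render a scene; returns ``(image, mask)``.

    ``mask`` is the exact rasterized cell region (pixel centers inside the
    analytic boundary; interior holes count as foreground).  A separate
    ``noise_rng`` may be supplied so image sequences reuse the structural
    randomness (hole and distractor placement) while varying the noise.
    """
    h, w = spec.image_shape
    cx, cy = spec.cell_center
    margin = spec.halo_extent
    if (
        cx - spec.max_radius - margin < 0
        or cy - spec.max_radius - margin < 0
        or cx + spec.max_radius + margin > w - 1
        or cy + spec.max_radius + margin > h - 1
    ):
        raise ValueError("cell (with halo) exceeds the image bounds")

    rng = np.random.default_rng(spec.seed)
    if noise_rng is None:
        noise_rng = rng

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx = xx - cx
    dy = yy - cy
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    rb = _boundary_radius(spec, theta)
    d = rho - rb  # signed radial distance to the boundary (positive outside)
    mask = d <= 0.0

    img = np.full((h, w), spec.background_level, dtype=np.float64)
    img[mask] = spec.body_level

    # Interior dark patches ("holes" from intensity inhomogeneity).  The
    # first patch sits peripherally, close to the boundary — the placement
    # where inhomogeneity most disturbs edge detection; the rest are
    # uniform over the cell area.
    rmin = float(rb.min())
    cap = max(rmin - spec.hole_radius - 1.0, 0.0)
    for i in range(spec.hole_count):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        if i == 0:
            rad = cap * rng.uniform(0.85, 1.0)
        else:
            rad = cap * np.sqrt(rng.uniform(0.0, 1.0))
        hx = cx + rad * np.cos(ang)
        hy = cy + rad * np.sin(ang)
        patch = ((xx - hx) ** 2 + (yy - hy) ** 2 <= spec.hole_radius**2) & mask
        img[patch] = spec.body_level - spec.hole_depth

    # Edge contrast profile along the boundary.
    cf = _contrast_factor(spec, theta)

    # Body-edge fade on low-contrast arcs: intensity ramps toward background
    # near the inside of the boundary where the contrast factor is low; at the
    # lowest factors the ramp reaches the background level at the boundary, so
    # the raw cell/background step disappears there entirely.
    fade = np.clip((1.0 - cf) / 0.72, 0.0, 1.0) * (
        spec.background_level - spec.body_level
    )
    ramp = np.exp(-(d**2) / (2.0 * spec.edge_fade_width**2))
    img = np.where(mask, img + fade * ramp, img)

    # Phase halo: additive bright ridge outside the boundary, sharp inner
    # rise (halo_rise) and slow outer decay (halo_width), crest at
    # halo_peak_offset; amplitude scaled by the arc contrast profile.
    amp = cf * (spec.halo_level - spec.background_level)
    off = spec.halo_peak_offset
    prof = np.where(
        d < off,
        np.exp(-((d - off) ** 2) / (2.0 * spec.halo_rise**2)),
        np.exp(-((d - off) ** 2) / (2.0 * spec.halo_width**2)),
    )
    outside = ~mask & (d < spec.halo_extent + 3.0)
    img = np.where(outside, img + amp * prof, img)

    # Distractor blobs (other cells/debris) away from the cell: kept outside
    # the diagonal of any square ROI that just encloses the cell plus halo,
    # so a user-selected ROI around the cell contains only the target.
    exclusion = np.sqrt(2.0) * (float(rb.max()) + spec.halo_extent + 8.0)
    placed = 0
    attempts = 0
    while placed < spec.distractor_count and attempts < 200:
        attempts += 1
        bx = rng.uniform(spec.distractor_radius + 2.0, w - spec.distractor_radius - 3.0)
        by = rng.uniform(spec.distractor_radius + 2.0, h - spec.distractor_radius - 3.0)
        if np.hypot(bx - cx, by - cy) < exclusion + spec.distractor_radius:
            continue
        blob = (xx - bx) ** 2 + (yy - by) ** 2 <= spec.distractor_radius**2
        img[blob] = spec.body_level
        placed += 1

    if spec.blur_sigma > 0:
        img = ndi.gaussian_filter(img, spec.blur_sigma, mode="nearest")
    if spec.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, spec.noise_sigma, size=img.shape)
    np.clip(img, 0.0, 255.0, out=img)
    return img, mask


def make_cell_sequence(spec: SequenceSpec):
    """Render a sequence; returns ``(frames, masks)`` lists of length n_frames.

    The centroid follows the stated per-frame drift, the harmonic
    amplitudes follow a seeded random walk, hole/distractor placement is
    shared across frames (they move rigidly with the cell), and the noise
    realization is fresh per frame — except for a fully static spec (zero
    drift, zero walk scale), which replicates one frame exactly.  Raises
    if the cell would leave the frame.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.base
    coeffs = [list(c) for c in base.fourier_coeffs]
    amp_cap = 0.12 * base.base_radius
    # A fully static spec replicates one frame exactly (identical scene
    # parameters render identical frames, noise included).
    static = spec.drift == (0.0, 0.0) and spec.walk_scale == 0.0
    frames: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for i in range(spec.n_frames):
        center = (
            base.cell_center[0] + i * spec.drift[0],
            base.cell_center[1] + i * spec.drift[1],
        )
        scene = replace(
            base,
            cell_center=center,
            fourier_coeffs=tuple((k, a, p) for k, a, p in coeffs),
        )
        if static:
            noise_rng = np.random.default_rng(spec.seed)
        else:
            noise_rng = np.random.default_rng(rng.integers(0, 2**31))
        try:
            img, mask = make_cell_image(scene, noise_rng=noise_rng)
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
        frames.append(img)
        masks.append(mask)
        if spec.walk_scale > 0:
            for c in coeffs:
                c[1] = float(np.clip(c[1] + rng.normal(0.0, spec.walk_scale), 0.0, amp_cap))
    return frames, masks


def random_scene(seed: int, **overrides) -> SceneSpec:
    """Draw a randomized scene: boundary harmonics, hole layout, and one
    low-contrast arc with a factor in [0.25, 0.5].

    Keyword overrides are applied on top of the drawn spec.
    """
    rng = np.random.default_rng(seed)
    base_radius = overrides.pop("base_radius", 32.0)
    coeffs = tuple(
        (k, float(rng.uniform(0.0, 0.05 * base_radius * 2.0 / k)), float(rng.uniform(0.0, 2 * np.pi)))
        for k in range(2, 6)
    )
    t0 = float(rng.uniform(0.0, 2 * np.pi))
    span = float(rng.uniform(0.7, 1.6))
    fac = float(rng.uniform(0.25, 0.5))
    arcs = [(t0, t0 + span, fac)]
    return SceneSpec(
        base_radius=base_radius,
        fourier_coeffs=coeffs,
        low_contrast_arcs=tuple(arcs),
        seed=int(rng.integers(0, 2**31)),
        **overrides,
    )
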