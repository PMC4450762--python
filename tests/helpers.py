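"""Shared independent reference implementations ("oracles") for the tests.

Everything here is deliberately written the slow, obvious way, without
reusing the package's own code paths.
"""

import numpy as np
from scipy.ndimage import grey_dilation


def geodesic_dilation_fixpoint(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Brute-force gray-scale reconstruction by dilation: iterate
    min(dilate3x3(J), I) until nothing changes."""
    cur = np.minimum(np.asarray(marker, float), np.asarray(mask, float))
    mask = np.asarray(mask, float)
    while True:
        nxt = np.minimum(grey_dilation(cur, footprint=np.ones((3, 3))), mask)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def bilinear_clamped(u: np.ndarray, x: float, y: float) -> float:
    """Scalar bilinear interpolation with border clamping."""
    h, w = u.shape
    x = min(max(x, 0.0), w - 1.0)
    y = min(max(y, 0.0), h - 1.0)
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
    fx, fy = x - x0, y - y0
    return (
        u[y0, x0] * (1 - fx) * (1 - fy)
        + u[y0, x1] * fx * (1 - fy)
        + u[y1, x0] * (1 - fx) * fy
        + u[y1, x1] * fx * fy
    )


def snake_step_reference(points, u, v, alpha, beta, gamma, h):
    """One explicit snake iteration as a plain scalar loop.

    Implements x_i^{n+1} = x_i^n + gamma*(alpha*d2 - beta*d4 + u(x_i, y_i))
    with periodic second/fourth differences divided by h^2 / h^4.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    out = np.empty_like(pts)
    for i in range(n):
        xm2, xm1 = pts[(i - 2) % n], pts[(i - 1) % n]
        xp1, xp2 = pts[(i + 1) % n], pts[(i + 2) % n]
        d2 = (xp1 - 2 * pts[i] + xm1) / h**2
        d4 = (xp2 - 4 * xp1 + 6 * pts[i] - 4 * xm1 + xm2) / h**4
        ext = np.array(
            [bilinear_clamped(u, pts[i, 0], pts[i, 1]), bilinear_clamped(v, pts[i, 0], pts[i, 1])]
        )
        out[i] = pts[i] + gamma * (alpha * d2 - beta * d4 + ext)
    return out


def polygon_set_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric max distance between two closed polylines (as point sets:
    vertices of each against the segments of the other)."""

    def points_to_polyline(pts, poly):
        closed = np.vstack([poly, poly[:1]])
        best = np.full(len(pts), np.inf)
        for p0, p1 in zip(closed[:-1], closed[1:]):
            d = p1 - p0
            L2 = float(d @ d)
            if L2 > 0:
                t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
            else:
                t = np.zeros(len(pts))
            proj = p0 + t[:, None] * d
            best = np.minimum(best, np.linalg.norm(pts - proj, axis=1))
        return float(best.max())

    return max(points_to_polyline(a, b), points_to_polyline(b, a))


def random_star_contour(rng, n=32, radius=10.0, wobble=2.0, center=(16.0, 16.0)):
    """Random star-shaped closed contour with distinct, CCW-ordered points."""
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False) + rng.uniform(-0.02, 0.02, n)
    r = radius + rng.uniform(-wobble, wobble, n)
    return np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )
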