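"""Ellipse geometry helpers shared by the generator, tracker and FE mesher.

All functions work on an axis-aligned ellipse centred at the origin with
semi-axes ``a`` (x, major) and ``b`` (y, minor), lengths in mm.
"""

from __future__ import annotations

import numpy as np


def ellipse_point(theta: float | np.ndarray, a: float, b: float) -> np.ndarray:
    """Point(s) on the ellipse at parametric angle theta, shape (..., 2)."""
    theta = np.asarray(theta, dtype=float)
    return np.stack([a * np.cos(theta), b * np.sin(theta)], axis=-1)


def ellipse_outward_normal(theta: float | np.ndarray, a: float, b: float) -> np.ndarray:
    """Unit outward normal at parametric angle theta, shape (..., 2)."""
    theta = np.asarray(theta, dtype=float)
    n = np.stack([b * np.cos(theta), a * np.sin(theta)], axis=-1)
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def nearest_point_on_ellipse(p, a: float, b: float, n_iter: int = 60):
    """Nearest point on the ellipse to ``p`` and its parametric angle.

    Golden-section refinement of the squared distance over the parametric
    angle, started from the angle of the radially scaled point.  Robust for
    points inside and outside; accuracy far below a micrometre for the
    uterine scales used here.
    """
    p = np.asarray(p, dtype=float)
    t0 = np.arctan2(p[1] * a, p[0] * b)
    lo, hi = t0 - 0.6, t0 + 0.6

    def d2(t):
        return (a * np.cos(t) - p[0]) ** 2 + (b * np.sin(t) - p[1]) ** 2

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc, fd = d2(c), d2(d)
    for _ in range(n_iter):
        if fc < fd:
            hi, d, fd = d, c, fc
            c = hi - invphi * (hi - lo)
            fc = d2(c)
        else:
            lo, c, fc = c, d, fd
            d = lo + invphi * (hi - lo)
            fd = d2(d)
    t = 0.5 * (lo + hi)
    return ellipse_point(t, a, b), t


def signed_distance_to_ellipse(p, a: float, b: float) -> float:
    """Signed Euclidean distance from ``p`` to the ellipse (positive outside)."""
    p = np.asarray(p, dtype=float)
    q, _ = nearest_point_on_ellipse(p, a, b)
    dist = float(np.linalg.norm(p - q))
    inside = (p[0] / a) ** 2 + (p[1] / b) ** 2 < 1.0
    return -dist if inside else dist


def circle_circle_intersection(c0, r0: float, c1, r1: float, side: int = +1):
    """Intersection of two circles; picks the solution on the requested side.

    ``side=+1`` returns the intersection for which the cross product
    (c1-c0) x (p-c0) is positive.  Raises ValueError when the circles do
    not intersect.
    """
    c0 = np.asarray(c0, dtype=float)
    c1 = np.asarray(c1, dtype=float)
    d = float(np.linalg.norm(c1 - c0))
    if d > r0 + r1 or d < abs(r0 - r1) or d == 0.0:
        raise ValueError(
            f"circles do not intersect (d={d:.6g}, r0={r0:.6g}, r1={r1:.6g})"
        )
    ex = (c1 - c0) / d
    ey = np.array([-ex[1], ex[0]])
    x = (d * d + r0 * r0 - r1 * r1) / (2.0 * d)
    h2 = r0 * r0 - x * x
    h = np.sqrt(max(h2, 0.0))
    return c0 + x * ex + side * h * ey
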