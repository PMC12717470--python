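"""Low-level 3D primitives: point/segment distances, segment/segment
distances, and uniform sampling in ellipsoids.

Everything is vectorised over the *second* operand (one query object against
an array of segments), which is the access pattern of the growth loop.
"""

from __future__ import annotations

import numpy as np

_EPS = 1.0e-12


def point_segment_distance(point, p0, p1):
    """Euclidean distance from ``point`` (3,) to each segment ``p0[i]->p1[i]``.

    Degenerate (zero-length) segments are treated as points.
    """
    point = np.asarray(point, dtype=float)
    p0 = np.atleast_2d(np.asarray(p0, dtype=float))
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    d = p1 - p0
    dd = np.einsum("ij,ij->i", d, d)
    t = np.einsum("ij,ij->i", point[None, :] - p0, d) / np.where(dd < _EPS, 1.0, dd)
    t = np.clip(np.where(dd < _EPS, 0.0, t), 0.0, 1.0)
    closest = p0 + t[:, None] * d
    return np.linalg.norm(point[None, :] - closest, axis=1)


def segment_segments_distance(a0, a1, b0, b1):
    """Minimum distance between segment ``a0->a1`` and each segment
    ``b0[i]->b1[i]``.

    Vectorised form of the clamped closest-point-between-segments solution;
    degenerate segments fall back to point distances.
    """
    a0 = np.asarray(a0, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    b0 = np.atleast_2d(np.asarray(b0, dtype=float))
    b1 = np.atleast_2d(np.asarray(b1, dtype=float))

    d1 = a1 - a0                      # (3,)
    d2 = b1 - b0                      # (n,3)
    r = a0[None, :] - b0              # (n,3)

    a = float(np.dot(d1, d1))
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = r @ d1
    b = d2 @ d1
    denom = a * e - b * b

    # General case.
    s = np.where(denom > _EPS, np.clip((b * f - c * e) / np.where(denom > _EPS, denom, 1.0), 0.0, 1.0), 0.0)
    e_safe = np.where(e < _EPS, 1.0, e)
    t = (b * s + f) / e_safe

    # Clamp t, then recompute s where t was clamped.
    t_low = t < 0.0
    t_high = t > 1.0
    a_safe = a if a > _EPS else 1.0
    s = np.where(t_low, np.clip(-c / a_safe, 0.0, 1.0), s)
    s = np.where(t_high, np.clip((b - c) / a_safe, 0.0, 1.0), s)
    t = np.clip(t, 0.0, 1.0)

    # Degenerate operands.
    if a <= _EPS:
        s = np.zeros_like(t)
        t = np.clip(f / e_safe, 0.0, 1.0)
    t = np.where(e < _EPS, 0.0, t)

    c1 = a0[None, :] + s[:, None] * d1[None, :]
    c2 = b0 + t[:, None] * d2
    return np.linalg.norm(c1 - c2, axis=1)


def points_segments_min_distance(points, p0, p1):
    """Min distance from each of m points to the nearest of n segments.

    Broadcasted (m, n) evaluation; fine for the batch sizes of the growth
    loop (tens of points against a few hundred segments).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))  # (m,3)
    p0 = np.atleast_2d(np.asarray(p0, dtype=float))       # (n,3)
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    d = p1 - p0                                           # (n,3)
    dd = np.einsum("ij,ij->i", d, d)                      # (n,)
    diff = pts[:, None, :] - p0[None, :, :]               # (m,n,3)
    t = np.einsum("mnj,nj->mn", diff, d) / np.where(dd < _EPS, 1.0, dd)
    t = np.clip(np.where(dd[None, :] < _EPS, 0.0, t), 0.0, 1.0)
    closest = p0[None, :, :] + t[..., None] * d[None, :, :]
    dist = np.linalg.norm(pts[:, None, :] - closest, axis=2)
    return dist.min(axis=1)


def uniform_ball(rng, n=None):
    """Uniform samples in the unit ball; shape (3,) for ``n=None`` else (n,3)."""
    m = 1 if n is None else int(n)
    x = rng.normal(size=(m, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    radii = rng.random(m) ** (1.0 / 3.0)
    pts = x * radii[:, None]
    return pts[0] if n is None else pts


def sample_in_ellipsoid(rng, semi_axes, n=None):
    """Uniform samples inside an origin-centred, axis-aligned ellipsoid."""
    return uniform_ball(rng, n) * np.asarray(semi_axes, dtype=float)


def ellipsoid_surface_point(semi_axes, direction):
    """Intersection of ray ``t*direction`` (t>0) with the ellipsoid surface."""
    u = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(u)
    if norm <= 0:
        raise ValueError("direction must be a non-zero vector")
    u = u / norm
    semi = np.asarray(semi_axes, dtype=float)
    t = 1.0 / np.sqrt(np.sum((u / semi) ** 2))
    return t * u


def in_ellipsoid(points, semi_axes, tol=1.0e-12):
    """Boolean mask of points lying inside (or on) the ellipsoid."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    semi = np.asarray(semi_axes, dtype=float)
    return np.sum((pts / semi) ** 2, axis=1) <= 1.0 + tol
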