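"""Planar rigid-body geometry: rotations, least-squares superposition, ellipse rings."""

from __future__ import annotations

import numpy as np


class ImproperRotationError(ValueError):
    """The optimal orthogonal superposition is a reflection, not a rotation."""


def rotation_matrix(angle: float) -> np.ndarray:
    """2x2 counter-clockwise rotation matrix for ``angle`` in radians."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def ellipse_ring(semi_axes: tuple[float, float], n: int) -> np.ndarray:
    """Body-frame coordinates of ``n`` particles on an ellipse.

    The wide (long) semi-axis lies along the body x axis.  Particles are
    spaced at equal arc length (not equal parameter angle), so the surface
    particle density is uniform — uniform parameter spacing would crowd
    particles at the high-curvature narrow tips and bias any contact
    interaction toward them.
    """
    a, b = semi_axes
    t = np.linspace(0.0, 2.0 * np.pi, 4096)
    speed = np.sqrt((a * np.sin(t)) ** 2 + (b * np.cos(t)) ** 2)
    arc = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(t))])
    targets = arc[-1] * np.arange(n) / n
    tn = np.interp(targets, arc, t)
    return np.column_stack([a * np.cos(tn), b * np.sin(tn)])


def planar_rotation_fit(reference: np.ndarray, current: np.ndarray) -> float:
    """Least-squares planar rotation angle (radians) aligning ``reference``
    onto ``current`` about their centroids (2D Kabsch).

    Raises
    ------
    ImproperRotationError
        If a reflection superposes the point sets strictly better than any
        proper rotation (determinant test on the orthogonal Procrustes
        solution).  A silent angle would be meaningless for a mirrored body.
    ValueError
        If fewer than 2 points or degenerate (all-coincident) geometry.
    """
    ref = np.asarray(reference, dtype=float)
    cur = np.asarray(current, dtype=float)
    if ref.shape != cur.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("point sets must be matching (N, 2) arrays")
    if ref.shape[0] < 2:
        raise ValueError("need at least 2 points to fit a rotation")
    r = ref - ref.mean(axis=0)
    c = cur - cur.mean(axis=0)
    if not (np.any(np.abs(r) > 1e-12) and np.any(np.abs(c) > 1e-12)):
        raise ValueError("degenerate geometry: all points coincide with the centroid")
    # covariance H = sum_i c_i r_i^T ; proper rotation angle from its moments
    h = c.T @ r
    u, _, vt = np.linalg.svd(h)
    if np.linalg.det(u @ vt) < 0:
        raise ImproperRotationError(
            "reflection-optimal superposition: body appears mirrored relative to reference"
        )
    # angle of R maximizing trace(R^T H): atan2 over the cross/dot sums
    dot = h[0, 0] + h[1, 1]
    cross = h[1, 0] - h[0, 1]
    return float(np.arctan2(cross, dot))


def minimum_image(delta: np.ndarray, box: float) -> np.ndarray:
    """Wrap displacement vector(s) into the minimum-image convention."""
    return delta - box * np.round(np.asarray(delta, dtype=float) / box)


def wrap_angle(angle: float | np.ndarray) -> np.ndarray:
    """Wrap angle(s) into (-pi, pi]."""
    return -((-np.asarray(angle) + np.pi) % (2.0 * np.pi) - np.pi)
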