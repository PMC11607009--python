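"""Rotation-axis fitting and discrete candidate generation.

The three collinear column markers define the mechanical rotation axis of
the wheel arms. The axis is fitted as the 3D total-least-squares line
through the marker centroids (principal direction of the centred points).
Every wheel fiducial then moves on a circle around that axis; the device's
discrete stops turn the circle into ``positions_per_wheel`` candidate
points, generated by rotating the home (scanned) position in steps of
``angular_step_deg``.

Rotation convention: positive angles follow the right-hand rule about the
axis direction vector, i.e. the motion appears clockwise when sighting
along the direction vector (axis pointing away from the viewer). For the
+z axis, ``(1, 0, 0)`` rotated by +90 deg maps to ``(0, 1, 0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateAxisError, DegenerateOrbitError
from .geometry import DeviceGeometry

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class LineAxis:
    """A fitted 3D line: unit ``direction`` through ``pivot``.

    ``fit_residual`` is the RMS perpendicular distance of the fit points to
    the line (0 for exactly collinear input).
    """

    direction: np.ndarray  # (3,), unit norm
    pivot: np.ndarray  # (3,), mm
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        p = np.asarray(self.pivot, dtype=float)
        if d.shape != (3,) or p.shape != (3,):
            raise ValueError("direction and pivot must be 3-vectors")
        n = np.linalg.norm(d)
        if n == 0:
            raise DegenerateAxisError("axis direction has zero norm")
        object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "pivot", p)
        if self.fit_residual < 0:
            raise ValueError("fit_residual must be non-negative")

    def distance_to(self, points: np.ndarray) -> np.ndarray:
        """Perpendicular distance (mm) of one or more points to the line."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        v = pts - self.pivot
        along = v @ self.direction
        perp_sq = np.einsum("ij,ij->i", v, v) - along**2
        d = np.sqrt(np.maximum(perp_sq, 0.0))
        return d if np.asarray(points).ndim == 2 else float(d[0])

    def axial_coordinate(self, points: np.ndarray) -> np.ndarray:
        """Signed coordinate of points along the axis, measured from pivot."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        t = (pts - self.pivot) @ self.direction
        return t if np.asarray(points).ndim == 2 else float(t[0])


def fit_axis(points: np.ndarray) -> LineAxis:
    """Fit the rotation axis through >= 2 distinct points, least squares.

    The pivot is the centroid; the direction is the dominant principal
    direction of the centred points (first right singular vector), with the
    sign fixed so that the component of largest magnitude is positive. The
    residual is the RMS perpendicular distance to the fitted line.

    Raises
    ------
    DegenerateAxisError
        If fewer than two distinct points are given (all coincident).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise DegenerateAxisError("axis fit needs at least two 3D points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    # Scale-aware coincidence check: spread negligible vs. coordinates.
    scale = max(1.0, float(np.abs(pts).max()))
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] <= 1e-12 * scale:
        raise DegenerateAxisError("all points coincide; axis undefined")
    direction = vt[0]
    # Sign rule: largest-magnitude component positive (PCA sign ambiguity).
    k = int(np.argmax(np.abs(direction)))
    if direction[k] < 0:
        direction = -direction
    # explicit perpendicular component: no catastrophic cancellation for
    # exactly collinear input (residual comes out exactly 0)
    perp = centred - np.outer(centred @ direction, direction)
    residual = float(np.sqrt(np.einsum("ij,ij->i", perp, perp).mean()))
    return LineAxis(direction=direction, pivot=centroid, fit_residual=residual)


def rotate_about_axis(point: np.ndarray, axis: LineAxis, theta_deg: float) -> np.ndarray:
    """Rotate a point (or array of points) about an arbitrary 3D line.

    Implemented in Rodrigues axis-angle form about the unit direction
    ``k`` through the pivot ``p``::

        v' = v cos(t) + (k x v) sin(t) + k (k . v)(1 - cos(t)),  v = x - p

    Positive ``theta_deg`` is a right-hand rotation about ``k`` (clockwise
    when sighting along ``k``). Distance to the axis and the axial
    coordinate are preserved to floating precision.
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    v = np.atleast_2d(p) - axis.pivot
    k = axis.direction
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    rotated = v * c + np.cross(np.broadcast_to(k, v.shape), v) * s + np.outer(v @ k, k) * (1 - c)
    out = rotated + axis.pivot
    return out[0] if single else out


def rotate_about_axis_expanded(
    point: np.ndarray, axis: LineAxis, theta_deg: float
) -> np.ndarray:
    """Scalar expansion of the arbitrary-axis rotation.

    Fully expanded affine form of the same rotation as
    :func:`rotate_about_axis`, written out component by component
    (direction ``(i,j,k)``, pivot ``(p,q,r)``, point ``(x,y,z)``). Kept as
    an independent code path: the two implementations are asserted equal in
    the test suite, guarding against transcription slips in the long
    formula.
    """
    i, j, k = axis.direction
    p, q, r = axis.pivot
    pt = np.asarray(point, dtype=float)
    single = pt.ndim == 1
    pts = np.atleast_2d(pt)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    xp = (p * (j * j + k * k) - i * (q * j + r * k - i * x - j * y - k * z)) * (1 - c) \
        + x * c + (-r * j + q * k - k * y + j * z) * s
    yp = (q * (i * i + k * k) - j * (p * i + r * k - i * x - j * y - k * z)) * (1 - c) \
        + y * c + (r * i - p * k + k * x - i * z) * s
    zp = (r * (i * i + j * j) - k * (p * i + q * j - i * x - j * y - k * z)) * (1 - c) \
        + z * c + (-q * i + p * j - j * x + i * y) * s
    out = np.stack([xp, yp, zp], axis=1)
    return out[0] if single else out


@dataclass(frozen=True)
class CandidateSet:
    """The discrete rotational positions of one wheel's fiducial.

    ``candidates[k-1]`` is stop ``k``; stop 1 is the home (scanned)
    position, stored bit-identically to the input home point.
    """

    wheel_id: str
    home: np.ndarray  # (3,)
    candidates: np.ndarray  # (positions_per_wheel, 3)

    @property
    def n_positions(self) -> int:
        return self.candidates.shape[0]

    def position(self, index: int) -> np.ndarray:
        """Candidate point for 1-based stop ``index``."""
        if not 1 <= index <= self.n_positions:
            raise IndexError(f"position index {index} outside [1, {self.n_positions}]")
        return self.candidates[index - 1]


def generate_candidates(
    home: np.ndarray, axis: LineAxis, geometry: DeviceGeometry, wheel_id: str = ""
) -> CandidateSet:
    """Generate all discrete stop positions of one wheel fiducial.

    Candidate ``k`` is the home point rotated by ``(k-1) * angular_step_deg``
    about the fitted axis; candidate 1 is the home point itself, exactly.

    Raises
    ------
    DegenerateOrbitError
        If the home point lies on the axis (perpendicular distance
        <= 1e-3 mm): its orbit would collapse to a point.
    """
    home = np.asarray(home, dtype=float)
    if axis.distance_to(home) <= 1e-3:
        raise DegenerateOrbitError(
            f"home position {home} lies on the rotation axis; orbit degenerate"
        )
    n = geometry.positions_per_wheel
    cands = np.empty((n, 3), dtype=float)
    cands[0] = home
    for k in range(1, n):
        cands[k] = rotate_about_axis(home, axis, k * geometry.angular_step_deg)
    return CandidateSet(wheel_id=wheel_id, home=home.copy(), candidates=cands)
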