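"""Frame conventions, rigid-motion operators, and convex test volumes.

All coordinates live in the isocentric machine frame (IEC-style), in cm:

* ``x1`` — lateral (patient left/right),
* ``x2`` — vertical (up positive),
* ``x3`` — longitudinal (toward the gantry positive),

with the origin at the linac isocenter.  Gantry rotation turns points in
the ``x1``–``x2`` plane about the longitudinal axis; couch rotation turns
points in the ``x1``–``x3`` plane about the vertical axis.

Collision testing reduces to point-in-convex-volume queries built from a
single primitive: the signed dot product that classifies which side of a
plane a point lies on.  Boundary points (zero dot product, radial distance
exactly equal to a radius) are classified as *inside* — a collision test
must err on the conservative side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Classification tolerance for on-plane / on-surface decisions, cm.
ON_PLANE_TOL = 1e-9

__all__ = [
    "ON_PLANE_TOL",
    "GeometryError",
    "normalize_angle",
    "to_iec_scale",
    "gantry_rotation_matrix",
    "couch_rotation_matrix",
    "rotate_gantry_frame",
    "rotate_couch_frame",
    "plane_side",
    "translate_along",
    "Cylinder",
    "RectPrism",
    "TrapezoidPrism",
    "point_in_cylinder",
    "point_in_convex_prism",
]


class GeometryError(ValueError):
    """Raised for degenerate or invalid geometric input."""


# ---------------------------------------------------------------------------
# coordinate helpers


def as_point(p) -> np.ndarray:
    """Coerce to a float (3,) array and require finite values."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError("non-finite coordinates")
    return a


def as_points(ps) -> np.ndarray:
    """Coerce to a float (N, 3) array.  A single point becomes (1, 3)."""
    a = np.asarray(ps, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2 or a.shape[1] != 3:
        raise GeometryError(f"expected an (N, 3) array, got shape {a.shape}")
    return a


def normalize_angle(theta_deg: float) -> float:
    """Normalize an angle given on [-360, 360] degrees to (-180, 180].

    Machine readouts use the 0–360 display scale; internally every angle
    is reduced to the signed interval so that rotation composition and
    limit checks are unambiguous.
    """
    t = float(theta_deg)
    if not np.isfinite(t) or abs(t) > 360.0:
        raise GeometryError(f"angle {theta_deg!r} outside [-360, 360] degrees")
    t = t % 360.0
    if t > 180.0:
        t -= 360.0
    return t


def to_iec_scale(theta_deg: float) -> float:
    """Display an internal signed angle on the 0–360 machine scale."""
    return normalize_angle(theta_deg) % 360.0


# ---------------------------------------------------------------------------
# rotation / translation operators


def gantry_rotation_matrix(theta_deg: float) -> np.ndarray:
    """Rotation about the longitudinal axis ``x3`` (gantry rotation).

    ``[[c, -s, 0], [s, c, 0], [0, 0, 1]]`` with ``c = cos theta``,
    ``s = sin theta``; applied to every point of the gantry model.
    """
    t = np.deg2rad(normalize_angle(theta_deg))
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def couch_rotation_matrix(theta_deg: float) -> np.ndarray:
    """Rotation about the vertical axis ``x2`` (couch rotation).

    ``[[c, 0, -s], [0, 1, 0], [s, 0, c]]``; applied to every point of the
    couch model (and to patient points riding on the couch).
    """
    t = np.deg2rad(normalize_angle(theta_deg))
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def _apply_matrix(points, matrix: np.ndarray):
    a = np.asarray(points, dtype=float)
    single = a.ndim == 1
    out = as_points(a) @ matrix.T
    return out[0] if single else out


def rotate_gantry_frame(points, theta_deg: float):
    """Rotate point(s) by the gantry rotation matrix about the isocenter."""
    return _apply_matrix(points, gantry_rotation_matrix(theta_deg))


def rotate_couch_frame(points, theta_deg: float):
    """Rotate point(s) by the couch rotation matrix about the isocenter."""
    return _apply_matrix(points, couch_rotation_matrix(theta_deg))


def plane_side(a, b, p):
    """Signed side of the plane through ``a`` with normal ``b - a``.

    Returns ``AB . AP``: positive when ``p`` lies on the same side as the
    normal vector, zero on the plane, negative on the far side.  Accepts a
    single point or an (N, 3) batch for ``p``.
    """
    a = as_point(a)
    b = as_point(b)
    n = b - a
    if np.linalg.norm(n) <= ON_PLANE_TOL:
        raise GeometryError("degenerate plane normal: a == b")
    pts = np.asarray(p, dtype=float)
    single = pts.ndim == 1
    out = (as_points(pts) - a) @ n
    return float(out[0]) if single else out


def unit_direction(d) -> np.ndarray:
    d = as_point(d)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise GeometryError(f"direction {d} is not unit norm")
    return d


def translate_along(points, m: float, d):
    """Shift point(s) by magnitude ``m`` (cm) along unit direction ``d``."""
    d = unit_direction(d)
    a = np.asarray(points, dtype=float)
    single = a.ndim == 1
    out = as_points(a) + float(m) * d
    return out[0] if single else out


# ---------------------------------------------------------------------------
# convex test volumes


@dataclass(frozen=True)
class Cylinder:
    """Finite circular cylinder given by two axis points and a radius.

    Equivalent to the three-point representation (two axis points plus one
    circumference point fixing the radius) used for the gantry-head parts.
    """

    axis_start: np.ndarray
    axis_end: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "axis_start", as_point(self.axis_start))
        object.__setattr__(self, "axis_end", as_point(self.axis_end))
        if self.radius <= 0:
            raise GeometryError(f"cylinder radius must be positive, got {self.radius}")
        if np.linalg.norm(self.axis_end - self.axis_start) <= ON_PLANE_TOL:
            raise GeometryError("cylinder axis points coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.axis_end - self.axis_start))

    @property
    def axis_direction(self) -> np.ndarray:
        v = self.axis_end - self.axis_start
        return v / np.linalg.norm(v)

    def contains(self, points, margin: float = 0.0) -> np.ndarray:
        """Boundary-inclusive containment, optionally inflated by ``margin``.

        A point is inside when it lies between the two cap planes (dot
        product with the axis direction) and its perpendicular distance to
        the axis does not exceed the radius.
        """
        pts = as_points(points)
        u = self.axis_direction
        rel = pts - self.axis_start
        t = rel @ u
        radial = np.linalg.norm(rel - t[:, None] * u, axis=1)
        lo, hi = -margin - ON_PLANE_TOL, self.length + margin + ON_PLANE_TOL
        return (t >= lo) & (t <= hi) & (radial <= self.radius + margin + ON_PLANE_TOL)


# Face loops of an 8-corner hexahedron: corners 0-3 form one face loop,
# corners 4-7 the opposite loop, with edges i <-> i+4 joining them.
_HEX_FACES = (
    (0, 1, 2, 3),
    (7, 6, 5, 4),
    (0, 4, 5, 1),
    (1, 5, 6, 2),
    (2, 6, 7, 3),
    (3, 7, 4, 0),
)


def _newell_normal(quad: np.ndarray) -> np.ndarray:
    """Robust polygon normal (Newell's method) for a planar quad."""
    n = np.zeros(3)
    for i in range(4):
        p, q = quad[i], quad[(i + 1) % 4]
        n[0] += (p[1] - q[1]) * (p[2] + q[2])
        n[1] += (p[2] - q[2]) * (p[0] + q[0])
        n[2] += (p[0] - q[0]) * (p[1] + q[1])
    norm = np.linalg.norm(n)
    if norm <= ON_PLANE_TOL:
        raise GeometryError("degenerate prism face")
    return n / norm


@dataclass(frozen=True)
class ConvexPrism:
    """Convex hexahedron given by 8 corners; containment via six dot products.

    For each face an outward normal is derived from the corners; a point is
    inside iff every face-plane dot product places it on the interior side
    (boundary inclusive).
    """

    corners: np.ndarray
    _face_points: np.ndarray = field(init=False, repr=False, compare=False)
    _face_normals: np.ndarray = field(init=False, repr=False, compare=False)

    # geometric validation tolerance (construction only), cm
    _PLANAR_TOL = 1e-6

    def __post_init__(self):
        c = np.asarray(self.corners, dtype=float)
        if c.shape != (8, 3):
            raise GeometryError(f"prism needs 8 corners, got shape {c.shape}")
        if not np.all(np.isfinite(c)):
            raise GeometryError("non-finite prism corner")
        object.__setattr__(self, "corners", c)
        centroid = c.mean(axis=0)
        face_points = np.empty((6, 3))
        face_normals = np.empty((6, 3))
        for k, idx in enumerate(_HEX_FACES):
            quad = c[list(idx)]
            n = _newell_normal(quad)
            fp = quad.mean(axis=0)
            if n @ (centroid - fp) > 0:  # orient outward
                n = -n
            # face planarity
            if np.max(np.abs((quad - fp) @ n)) > self._PLANAR_TOL:
                raise GeometryError(f"prism face {idx} is not planar")
            face_points[k] = fp
            face_normals[k] = n
        # convexity: every corner on or inside every face plane
        d = (c[:, None, :] - face_points[None, :, :] * 1.0)
        signed = np.einsum("ijk,jk->ij", d, face_normals)
        if signed.max() > self._PLANAR_TOL:
            raise GeometryError("corner set is not convex")
        object.__setattr__(self, "_face_points", face_points)
        object.__setattr__(self, "_face_normals", face_normals)

    @property
    def face_planes(self):
        """(face point, outward unit normal) pairs for the six faces."""
        return list(zip(self._face_points, self._face_normals))

    def contains(self, points, margin: float = 0.0) -> np.ndarray:
        pts = as_points(points)
        signed = np.einsum("ijk,jk->ij", pts[:, None, :] - self._face_points[None], self._face_normals)
        return np.all(signed <= margin + ON_PLANE_TOL, axis=1)


@dataclass(frozen=True)
class RectPrism(ConvexPrism):
    """Rectangular prism (all faces rectangles) for imaging devices."""

    def __post_init__(self):
        super().__post_init__()
        # rectangular faces: adjacent edges orthogonal and opposite edges equal
        for idx in _HEX_FACES:
            quad = self.corners[list(idx)]
            e = np.diff(np.vstack([quad, quad[:1]]), axis=0)
            if abs(e[0] @ e[1]) > 1e-6 * max(1.0, np.linalg.norm(e[0]) * np.linalg.norm(e[1])):
                raise GeometryError(f"prism face {idx} is not rectangular")


@dataclass(frozen=True)
class TrapezoidPrism(ConvexPrism):
    """Convex hexahedron with two parallel faces (couch-top shape).

    Corners 0–3 and 4–7 are the two parallel face loops (for the couch:
    bottom and top surfaces), joined by edges ``i`` – ``i + 4``.
    """

    def __post_init__(self):
        super().__post_init__()
        n0 = _newell_normal(self.corners[[0, 1, 2, 3]])
        n1 = _newell_normal(self.corners[[4, 5, 6, 7]])
        if np.linalg.norm(np.cross(n0, n1)) > 1e-6:
            raise GeometryError("faces 0-3 and 4-7 are not parallel")


def point_in_cylinder(p, cylinder: Cylinder) -> bool | np.ndarray:
    """Boundary-inclusive point-in-cylinder test (cap planes + radial distance)."""
    pts = np.asarray(p, dtype=float)
    out = cylinder.contains(pts)
    return bool(out[0]) if pts.ndim == 1 else out


def point_in_convex_prism(p, prism: ConvexPrism) -> bool | np.ndarray:
    """Boundary-inclusive point-in-prism test via six face dot products."""
    pts = np.asarray(p, dtype=float)
    out = prism.contains(pts)
    return bool(out[0]) if pts.ndim == 1 else out
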