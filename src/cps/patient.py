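"""Patient surface model: camera calibration, ICP refinement, merging.

The patient model combines two point clouds:

* the CT body contour, extracted from planning-CT structures — the
  accurate baseline;
* a depth-camera surface cloud, brought into the machine frame by a
  block-calibration transform and refined by rigid ICP against the CT
  contour.

The block calibration follows a six-step procedure on a plastic block of
known dimensions whose four corners A, B, C, D are identified in the raw
camera data: translate A to the origin; rotate AD onto the lateral unit
axis; roll about that axis to take AC onto the longitudinal axis and AB
onto the vertical axis; scale each aligned axis by the ratio of true to
observed edge length; and finally translate the origin from A to the
block center (the laser setup point).  Per-axis scaling makes the result
affine rather than rigid — deliberately, since depth cameras exhibit
axis-dependent scale error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import GeometryError, as_point, as_points

__all__ = [
    "PointCloud",
    "BlockObservation",
    "CameraCalibration",
    "RigidTransform",
    "ICPResult",
    "CalibrationError",
    "RegistrationError",
    "calibrate_from_block",
    "apply_calibration",
    "icp_register",
    "merge_clouds",
    "contours_to_cloud",
]


class CalibrationError(ValueError):
    """Degenerate calibration block observation."""


class RegistrationError(ValueError):
    """ICP cannot run on the given clouds."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class PointCloud:
    """A labelled cloud of 3-D points (cm).

    ``label`` names the source (``ct_contour``, ``camera``, ``merged``,
    ``phantom`` ...); merged clouds additionally carry a per-point
    ``point_labels`` array so the origin of each point stays queryable.
    """

    points: np.ndarray
    label: str = "cloud"
    point_labels: np.ndarray | None = None

    def __post_init__(self):
        self.points = as_points(self.points) if len(np.atleast_1d(self.points)) else np.empty((0, 3))
        if not np.all(np.isfinite(self.points)):
            raise GeometryError("point cloud contains non-finite coordinates")
        if self.point_labels is not None:
            self.point_labels = np.asarray(self.point_labels)
            if self.point_labels.shape != (len(self.points),):
                raise ValueError("point_labels length must match point count")

    def __len__(self) -> int:
        return len(self.points)

    def labels(self) -> np.ndarray:
        if self.point_labels is not None:
            return self.point_labels
        return np.full(len(self.points), self.label, dtype=object)

    def select(self, label: str) -> "PointCloud":
        mask = self.labels() == label
        return PointCloud(self.points[mask], label=label)

    def transformed(self, func, label: str | None = None) -> "PointCloud":
        return PointCloud(
            func(self.points),
            label=self.label if label is None else label,
            point_labels=self.point_labels,
        )


@dataclass(frozen=True)
class BlockObservation:
    """Raw-camera coordinates of the calibration block's reference corners.

    ``corner_a`` is the common origin corner; D, B, C lie along the three
    block edges whose true lengths are known.  ``true_edge_lengths`` maps
    to (AD, AB, AC) in cm and ``block_center_offset`` is the block-center
    position measured from corner A in the ideal (aligned, true-scale)
    frame.
    """

    corner_a: np.ndarray
    corner_b: np.ndarray
    corner_c: np.ndarray
    corner_d: np.ndarray
    true_edge_lengths: tuple[float, float, float]
    block_center_offset: np.ndarray

    def __post_init__(self):
        for key in ("corner_a", "corner_b", "corner_c", "corner_d", "block_center_offset"):
            object.__setattr__(self, key, as_point(getattr(self, key)))
        lengths = tuple(float(v) for v in self.true_edge_lengths)
        if len(lengths) != 3 or any(v <= 0 for v in lengths):
            raise CalibrationError("true_edge_lengths must be three positive lengths (AD, AB, AC)")
        object.__setattr__(self, "true_edge_lengths", lengths)
        m = np.stack([
            self.corner_d - self.corner_a,
            self.corner_b - self.corner_a,
            self.corner_c - self.corner_a,
        ])
        if np.linalg.matrix_rank(m, tol=1e-9) < 3:
            raise CalibrationError("corners are degenerate: AD, AB, AC must be linearly independent")


@dataclass(frozen=True)
class CameraCalibration:
    """Affine camera-to-machine transform: shift, rotate, scale, shift.

    Applied as ``p -> S R (p + t_pre) + t_post`` with ``R`` orthonormal
    (det +1) and ``S`` a positive per-axis diagonal scaling in the
    block-aligned frame.
    """

    translation_pre: np.ndarray
    rotation: np.ndarray
    per_axis_scale: np.ndarray
    translation_post: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "translation_pre", as_point(self.translation_pre))
        object.__setattr__(self, "translation_post", as_point(self.translation_post))
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise CalibrationError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise CalibrationError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        s = np.asarray(self.per_axis_scale, dtype=float)
        if s.shape != (3,) or np.any(s <= 0):
            raise CalibrationError("per_axis_scale must be three positive factors")
        object.__setattr__(self, "per_axis_scale", s)

    @classmethod
    def identity(cls) -> "CameraCalibration":
        return cls(np.zeros(3), np.eye(3), np.ones(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = (as_points(pts) + self.translation_pre) @ self.rotation.T
        out = out * self.per_axis_scale + self.translation_post
        return out[0] if single else out

    def invert(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = (as_points(pts) - self.translation_post) / self.per_axis_scale
        out = out @ self.rotation - self.translation_pre
        return out[0] if single else out


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R p + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", as_point(self.translation))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = as_points(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self`` after ``other``: (self o other)(p) = self(other(p))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# block calibration


def _rotation_between(v: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector ``v`` onto unit ``target``."""
    v = v / np.linalg.norm(v)
    axis = np.cross(v, target)
    s = np.linalg.norm(axis)
    c = float(v @ target)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to v
        helper = np.array([1.0, 0.0, 0.0])
        if abs(v[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(v, helper)
        axis /= np.linalg.norm(axis)
        return _rodrigues(axis, np.pi)
    axis /= s
    return _rodrigues(axis, np.arctan2(s, c))


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def calibrate_from_block(obs: BlockObservation) -> CameraCalibration:
    """Recover the camera-to-machine transform from one block observation.

    Steps: shift corner A to the origin; rotate edge AD onto the lateral
    unit axis ``Ux``; roll about ``Ux`` so that AC aligns with ``Uz`` (and
    AB, for an orthogonal block, with ``Uy``); derive per-axis scale
    factors from the known edge lengths; shift the origin to the block
    center.  Applying the result to the observed corners reproduces the
    ideal block corners (exactly, in the noise-free case).
    """
    ad = obs.corner_d - obs.corner_a
    ab = obs.corner_b - obs.corner_a
    ac = obs.corner_c - obs.corner_a

    r1 = _rotation_between(ad, np.array([1.0, 0.0, 0.0]))
    ac1 = r1 @ ac
    # roll about Ux bringing AC into the x-z plane with positive z
    h = np.hypot(ac1[1], ac1[2])
    if h < 1e-12:
        raise CalibrationError("corner C lies on the AD axis")
    theta = np.arctan2(ac1[1], ac1[2])
    r2 = _rodrigues(np.array([1.0, 0.0, 0.0]), theta)
    rotation = r2 @ r1

    len_ad, len_ab, len_ac = (np.linalg.norm(v) for v in (ad, ab, ac))
    true_ad, true_ab, true_ac = obs.true_edge_lengths
    scale = np.array([true_ad / len_ad, true_ab / len_ab, true_ac / len_ac])

    return CameraCalibration(
        translation_pre=-obs.corner_a,
        rotation=rotation,
        per_axis_scale=scale,
        translation_post=-obs.block_center_offset,
    )


def apply_calibration(cloud: PointCloud, cal: CameraCalibration) -> PointCloud:
    """Apply the calibration transform pointwise; count and labels kept."""
    return cloud.transformed(cal.apply)


# ---------------------------------------------------------------------------
# ICP


@dataclass
class ICPResult:
    transform: RigidTransform
    cost_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``source`` onto ``target``."""
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    H = (source - sc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, tc - R @ sc)


def icp_register(
    source: PointCloud | np.ndarray,
    target: PointCloud | np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-6,
    trim_fraction: float = 0.0,
) -> ICPResult:
    """Point-to-point ICP: nearest-neighbour matching + rigid Kabsch update.

    Returns the rigid transform mapping the source cloud onto the target
    along with the per-iteration RMS cost trace (non-increasing).  Stops
    when the relative cost change drops below ``tol`` or at ``max_iter``.
    ``trim_fraction`` optionally discards the worst correspondences each
    iteration (0 = plain ICP).
    """
    src = source.points if isinstance(source, PointCloud) else as_points(source)
    tgt = target.points if isinstance(target, PointCloud) else as_points(target)
    if len(src) == 0 or len(tgt) == 0:
        raise RegistrationError("both clouds must be nonempty")
    if len(src) < 3 or np.linalg.matrix_rank(src - src.mean(axis=0), tol=1e-9) < 2:
        raise RegistrationError("source cloud is degenerate (needs >= 3 non-collinear points)")
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must be in [0, 1)")

    tree = cKDTree(tgt)
    transform = RigidTransform.identity()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moved = transform.apply(src)
        dist, idx = tree.query(moved)
        if trim_fraction > 0.0:
            keep = max(3, int(np.ceil(len(dist) * (1.0 - trim_fraction))))
            order = np.argsort(dist)[:keep]
        else:
            order = slice(None)
        cost = float(np.sqrt(np.mean(dist[order] ** 2)))
        trace.append(cost)
        if cost <= tol:
            converged = True
            break
        update = _kabsch(moved[order], tgt[idx[order]])
        transform = update.compose(transform)
        if len(trace) >= 2:
            prev = trace[-2]
            if prev > 0 and abs(prev - cost) / prev < tol:
                converged = True
                break
    return ICPResult(transform=transform, cost_trace=trace, n_iterations=it, converged=converged)


# ---------------------------------------------------------------------------
# merging and contour ingestion


def merge_clouds(ct: PointCloud, camera: PointCloud) -> PointCloud:
    """Union of the CT-contour baseline and the camera cloud.

    No points are deleted: the CT contour is the accurate baseline and
    the camera cloud adds surface coverage beyond the scanned extent.
    Source labels are preserved per point.
    """
    points = np.vstack([ct.points, camera.points]) if len(ct) or len(camera) else np.empty((0, 3))
    labels = np.concatenate([ct.labels(), camera.labels()])
    return PointCloud(points, label="merged", point_labels=labels)


def contours_to_cloud(slices, step: float | None = None, label: str = "ct_contour") -> PointCloud:
    """Convert per-slice closed polygons to a 3-D point cloud.

    ``slices`` is an iterable of ``(z, vertices)`` with ``vertices`` an
    (N, 2) array of in-plane (lateral, vertical) coordinates forming a
    closed loop (an explicitly repeated first vertex is accepted and
    dropped).  With ``step`` set, each polygon edge is resampled at
    ``<= step`` spacing; otherwise the vertices are emitted as-is.
    """
    out = []
    for z, vertices in slices:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"slice z={z}: vertices must be (N, 2)")
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise ValueError(f"slice z={z}: polygon needs >= 3 distinct vertices (open contour?)")
        pts2 = []
        n = len(v)
        for i in range(n):
            p, q = v[i], v[(i + 1) % n]
            if step is None:
                pts2.append(p[None, :])
                continue
            edge_len = np.linalg.norm(q - p)
            k = max(int(np.ceil(edge_len / step)), 1)
            t = np.arange(k) / k
            pts2.append(p[None, :] + t[:, None] * (q - p)[None, :])
        flat = np.vstack(pts2)
        out.append(np.column_stack([flat[:, 0], flat[:, 1], np.full(len(flat), float(z))]))
    points = np.vstack(out) if out else np.empty((0, 3))
    return PointCloud(points, label=label)
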