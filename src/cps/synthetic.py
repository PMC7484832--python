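"""Synthetic inputs: calibration blocks, phantom clouds, collision scenes.

Every generator is a pure function of its spec and seed and emits its
ground truth (true corners, planted points, poses) alongside the data,
so downstream tests never have to re-derive it from the system under
test.  The phantoms stand in for the commercial QA devices used to
exercise collision systems: a cylindrical diode array (ArcCheck-class)
and an anthropomorphic body (Rando-class), here modelled as stacked
half-ellipsoids.

The noise model is isotropic per-point Gaussian displacement with
sigma = 0.3 cm by default, matching the ~3 mm spatial resolution of a
consumer depth camera at treatment-room distance; sensor-physics noise
(quantisation, edge artefacts) is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np

from .machine import MachineGeometry, MachineState, ImagerState, default_geometry, pose_machine
from .patient import BlockObservation, PointCloud, RigidTransform

__all__ = [
    "PhantomSpec",
    "BlockSample",
    "CalibrationCase",
    "Scene",
    "make_block",
    "make_block_observation",
    "make_cylinder_phantom",
    "make_humanoid_phantom",
    "make_scene",
    "write_cloud_with_sidecar",
]

#: default surface sampling density, points per cm^2
DEFAULT_DENSITY = 2.0
#: default per-point Gaussian noise, cm (camera-grade)
DEFAULT_NOISE = 0.3

_HUMANOID_DEFAULTS = {
    # (longitudinal semi-axis, lateral semi-axis, vertical semi-axis), cm;
    # textbook adult proportions, head toward +x3
    "head": (12.0, 8.0, 10.0),
    "torso": (30.0, 19.0, 12.0),
    "legs": (45.0, 14.0, 8.0),
    "gap": 2.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one synthetic phantom cloud."""

    kind: str = "cylinder"
    dimensions: dict = dc_field(default_factory=dict)
    pose: RigidTransform | None = None
    point_density: float = DEFAULT_DENSITY
    noise_sigma: float = DEFAULT_NOISE
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("block", "cylinder", "humanoid"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.point_density <= 0:
            raise ValueError("point_density must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        for k, v in self.dimensions.items():
            if k != "gap" and np.any(np.asarray(v, dtype=float) <= 0):
                raise ValueError(f"dimension {k}={v} must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def metadata(self) -> dict:
        d = asdict(self)
        if self.pose is not None:
            d["pose"] = {
                "rotation": self.pose.rotation.tolist(),
                "translation": self.pose.translation.tolist(),
            }
        return d


def _posed(points: np.ndarray, pose: RigidTransform | None) -> np.ndarray:
    return points if pose is None else pose.apply(points)


def _noisy(points: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return points
    return points + rng.normal(0.0, sigma, size=points.shape)


# ---------------------------------------------------------------------------
# calibration block


@dataclass(frozen=True)
class BlockSample:
    """A surface-sampled calibration block with its ground truth."""

    cloud: PointCloud
    clean_points: np.ndarray
    face_normals: np.ndarray  # outward normal of the face each point was drawn on
    corners: dict  # A, B, C, D reference corners plus all 8, posed


def _block_corners(dims: tuple[float, float, float]) -> np.ndarray:
    lx, ly, lz = dims
    return np.array([
        [0, 0, 0], [lx, 0, 0], [lx, ly, 0], [0, ly, 0],
        [0, 0, lz], [lx, 0, lz], [lx, ly, lz], [0, ly, lz],
    ], dtype=float)


def make_block(spec: PhantomSpec) -> BlockSample:
    """Surface-sample a rectangular block; corner A at the local origin.

    Reference corners: A = origin, D along the lateral edge, B along the
    vertical edge, C along the longitudinal edge (the three edges whose
    true lengths calibrate the per-axis scale).
    """
    if spec.kind != "block":
        raise ValueError("spec.kind must be 'block'")
    dims = tuple(float(v) for v in spec.dimensions.get("size", (30.0, 20.0, 10.0)))
    rng = spec.rng()
    lx, ly, lz = dims
    faces = [
        # (fixed axis, fixed value, outward normal sign)
        (0, 0.0, -1), (0, lx, 1),
        (1, 0.0, -1), (1, ly, 1),
        (2, 0.0, -1), (2, lz, 1),
    ]
    pts = []
    normals = []
    for axis, value, sign in faces:
        others = [i for i in range(3) if i != axis]
        spans = [dims[i] for i in others]
        n = max(int(round(spec.point_density * spans[0] * spans[1])), 1)
        uv = rng.uniform(size=(n, 2)) * np.array(spans)
        face_pts = np.zeros((n, 3))
        face_pts[:, axis] = value
        face_pts[:, others[0]] = uv[:, 0]
        face_pts[:, others[1]] = uv[:, 1]
        normal = np.zeros(3)
        normal[axis] = sign
        pts.append(face_pts)
        normals.append(np.tile(normal, (n, 1)))
    clean_local = np.vstack(pts)
    normals = np.vstack(normals)

    clean = _posed(clean_local, spec.pose)
    if spec.pose is not None:
        normals = normals @ spec.pose.rotation.T
    noisy = _noisy(clean, spec.noise_sigma, rng)

    corners8 = _posed(_block_corners(dims), spec.pose)
    corners = {
        "A": corners8[0],
        "D": corners8[1],  # end of the lateral edge from A
        "B": corners8[3],  # end of the vertical edge from A
        "C": corners8[4],  # end of the longitudinal edge from A
        "all": corners8,
    }
    return BlockSample(
        cloud=PointCloud(noisy, label="phantom"),
        clean_points=clean,
        face_normals=normals,
        corners=corners,
    )


@dataclass(frozen=True)
class CalibrationCase:
    """A forward-generated calibration problem with known answer."""

    observation: BlockObservation
    ideal_corners: dict  # A, B, C, D in the machine frame (block-centered)
    true_rotation: np.ndarray
    true_scale: np.ndarray


def _euler_xyz(angles_deg) -> np.ndarray:
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def make_block_observation(
    block_size=(30.0, 20.0, 10.0),
    rotation_deg=(0.0, 0.0, 0.0),
    scale=(1.0, 1.0, 1.0),
    translation=(0.0, 0.0, 0.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> CalibrationCase:
    """Generate a camera observation of the block under a known distortion.

    The camera is modelled as the inverse of the calibration: ideal
    corners are scaled down per axis, rotated, and shifted, producing the
    raw observation whose calibration should recover the inputs.
    """
    lx, ly, lz = (float(v) for v in block_size)
    rng = np.random.default_rng(seed)
    # ideal corner offsets from A in the machine frame: D lateral (x1),
    # B vertical (x2), C longitudinal (x3)
    ideal = {
        "A": np.zeros(3),
        "D": np.array([lx, 0.0, 0.0]),
        "B": np.array([0.0, ly, 0.0]),
        "C": np.array([0.0, 0.0, lz]),
    }
    R = _euler_xyz(rotation_deg)
    s = np.asarray(scale, dtype=float)
    t = np.asarray(translation, dtype=float)
    observed = {}
    for key, p in ideal.items():
        obs = R.T @ (p / s) + t
        if noise_sigma > 0:
            obs = obs + rng.normal(0.0, noise_sigma, size=3)
        observed[key] = obs
    center = np.array([lx / 2.0, ly / 2.0, lz / 2.0])
    obs = BlockObservation(
        corner_a=observed["A"],
        corner_b=observed["B"],
        corner_c=observed["C"],
        corner_d=observed["D"],
        true_edge_lengths=(lx, ly, lz),
        block_center_offset=center,
    )
    ideal_centered = {k: p - center for k, p in ideal.items()}
    return CalibrationCase(
        observation=obs,
        ideal_corners=ideal_centered,
        true_rotation=R,
        true_scale=s,
    )


# ---------------------------------------------------------------------------
# phantoms


def make_cylinder_phantom(spec: PhantomSpec) -> PointCloud:
    """Surface-sample a cylinder (lateral wall + both caps).

    Default dimensions follow a cylindrical QA array: diameter 26.6 cm,
    length 55 cm, axis along the local z (longitudinal) axis before the
    pose is applied.
    """
    if spec.kind != "cylinder":
        raise ValueError("spec.kind must be 'cylinder'")
    diameter = float(spec.dimensions.get("diameter", 26.6))
    length = float(spec.dimensions.get("length", 55.0))
    r = diameter / 2.0
    rng = spec.rng()

    n_side = max(int(round(spec.point_density * 2 * np.pi * r * length)), 1)
    phi = rng.uniform(0.0, 2 * np.pi, n_side)
    z = rng.uniform(-length / 2.0, length / 2.0, n_side)
    side = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

    n_cap = max(int(round(spec.point_density * np.pi * r * r)), 1)
    caps = []
    for zc in (-length / 2.0, length / 2.0):
        phi_c = rng.uniform(0.0, 2 * np.pi, n_cap)
        rad = r * np.sqrt(rng.uniform(size=n_cap))
        caps.append(np.column_stack([rad * np.cos(phi_c), rad * np.sin(phi_c), np.full(n_cap, zc)]))
    local = np.vstack([side] + caps)
    pts = _noisy(_posed(local, spec.pose), spec.noise_sigma, rng)
    return PointCloud(pts, label="phantom")


def _half_ellipsoid_surface(semi, n: int, rng: np.random.Generator) -> np.ndarray:
    """Upper-half (x2 >= 0) ellipsoid surface sample, mirror-symmetric in x1.

    Half the points are drawn on the x1 >= 0 side and mirrored, so the
    noiseless cloud is exactly bilaterally symmetric.
    """
    a3, a1, a2 = semi  # longitudinal, lateral, vertical semi-axes
    m = max(n // 2, 1)
    v = rng.normal(size=(m, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v[:, 1] = np.abs(v[:, 1])  # upper half (vertical component)
    v[:, 0] = np.abs(v[:, 0])  # one lateral side, mirrored below
    pts = np.column_stack([a1 * v[:, 0], a2 * v[:, 1], a3 * v[:, 2]])
    mirrored = pts * np.array([-1.0, 1.0, 1.0])
    return np.vstack([pts, mirrored])


def make_humanoid_phantom(spec: PhantomSpec) -> PointCloud:
    """Stacked half-ellipsoid body (head / torso / legs), supine.

    Each component is the upper half of an ellipsoid with its center on
    the couch-top plane (local ``x2 = 0``), so the maximum height above
    the plane equals the largest vertical semi-axis.  The head points
    toward local ``+x3``; the noiseless cloud is exactly symmetric about
    the sagittal plane ``x1 = 0``.
    """
    if spec.kind != "humanoid":
        raise ValueError("spec.kind must be 'humanoid'")
    dims = {**_HUMANOID_DEFAULTS, **spec.dimensions}
    rng = spec.rng()
    gap = float(dims["gap"])
    parts = []
    # stack along x3: head at the superior end, then torso, then legs
    z_top = 0.0
    for name in ("head", "torso", "legs"):
        a3, a1, a2 = (float(v) for v in dims[name])
        center_z = z_top - a3
        # Thomsen approximation of the ellipsoid surface area
        p = 1.6075
        ap, bp, cp = a1**p, a2**p, a3**p
        area = 4 * np.pi * ((ap * bp + ap * cp + bp * cp) / 3.0) ** (1.0 / p) / 2.0
        n = max(int(round(spec.point_density * area)), 2)
        local = _half_ellipsoid_surface((a3, a1, a2), n, rng)
        local[:, 2] += center_z
        parts.append(local)
        z_top = center_z - a3 - gap
    local = np.vstack(parts)
    # shift so the body spans x3 in [-(total length), 0] with head at 0
    pts = _noisy(_posed(local, spec.pose), spec.noise_sigma, rng)
    return PointCloud(pts, label="phantom")


# ---------------------------------------------------------------------------
# collision scenes


@dataclass(frozen=True)
class Scene:
    """One randomized machine state + phantom cloud (couch home frame)."""

    state: MachineState
    cloud: PointCloud
    expected_collision: bool | None
    forced_volume: str | None
    margin: float
    seed: int

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.cloud.points).tobytes())
        h.update(repr(self.state).encode())
        return h.hexdigest()


def _phantom_on_couch(rng: np.random.Generator, seed: int, lng: float, density: float) -> PointCloud:
    """A phantom resting on the couch top near the isocenter region."""
    kind = rng.choice(["cylinder", "humanoid"])
    if kind == "cylinder":
        diameter = float(rng.uniform(18.0, 30.0))
        pose = RigidTransform(
            np.eye(3),
            np.array([0.0, diameter / 2.0, -lng + rng.uniform(-10.0, 10.0)]),
        )
        spec = PhantomSpec(
            kind="cylinder",
            dimensions={"diameter": diameter, "length": float(rng.uniform(40.0, 70.0))},
            pose=pose,
            point_density=density,
            noise_sigma=0.0,
            seed=seed,
        )
        return make_cylinder_phantom(spec)
    pose = RigidTransform(np.eye(3), np.array([0.0, 0.0, -lng + 60.0 + rng.uniform(-10.0, 10.0)]))
    spec = PhantomSpec(kind="humanoid", pose=pose, point_density=density, noise_sigma=0.0, seed=seed)
    return make_humanoid_phantom(spec)


def make_scene(
    seed: int,
    mode: str = "random",
    geom: MachineGeometry | None = None,
    point_density: float = 1.0,
) -> Scene:
    """Seeded random collision scene.

    Modes: ``random`` (no expected verdict), ``forced_collision`` (one
    extra point planted strictly inside a named machine volume, so the
    verdict is known to be a collision naming that volume), and
    ``forced_clear`` (gantry up, devices retracted, phantom low: every
    test point is below the gantry clearance by construction, so the
    verdict is known to be clear).
    """
    if mode not in ("random", "forced_collision", "forced_clear"):
        raise ValueError(f"unknown scene mode {mode!r}")
    geom = geom or default_geometry()
    rng = np.random.default_rng(seed)
    margin = float(rng.choice([0.0, 0.0, 1.0, 2.0]))

    if mode == "forced_clear":
        # Gantry at 0 deg occupies the region above the lowest cap plane
        # (>= plane_offsets[0] above isocenter); with no devices deployed
        # and every couch/phantom point at x2 <= phantom height - VRT < 0
        # << plane_offsets[0], no containment test can fire.
        lng = float(rng.uniform(80.0, 140.0))
        state = MachineState(
            gantry_angle=0.0,
            couch_lat_readout=geom.lat_center_readout,
            couch_lng_readout=lng,
            couch_vrt_readout=float(rng.uniform(5.0, 30.0)),
            couch_rtn=float(rng.uniform(-45.0, 45.0)),
        )
        cloud = _phantom_on_couch(rng, seed, lng, point_density)
        return Scene(state, cloud, expected_collision=False, forced_volume=None,
                     margin=margin, seed=seed)

    lng = float(rng.uniform(60.0, 140.0))
    lat_disp = float(rng.uniform(-20.0, 20.0))
    center = geom.lat_center_readout
    lat_readout = center - lat_disp if lat_disp >= 0 else -lat_disp
    deploy_mv = bool(rng.uniform() < 0.4)
    deploy_kv = bool(rng.uniform() < 0.4)
    state = MachineState(
        gantry_angle=float(rng.uniform(0.0, 360.0)),
        couch_lat_readout=lat_readout,
        couch_lng_readout=lng,
        couch_vrt_readout=float(rng.uniform(5.0, 30.0)),
        couch_rtn=float(rng.uniform(-90.0, 90.0)),
        mv_imager=ImagerState(deployed=deploy_mv, vertical=float(rng.uniform(35.0, 50.0))),
        kv_arms=ImagerState(deployed=deploy_kv, vertical=float(rng.uniform(40.0, 55.0))),
    )
    cloud = _phantom_on_couch(rng, seed, lng, point_density)

    if mode == "random":
        return Scene(state, cloud, expected_collision=None, forced_volume=None,
                     margin=margin, seed=seed)

    # forced collision: plant a point strictly inside a named posed volume,
    # then pull it back into the couch home frame
    posed = pose_machine(geom, state, sampling=5.0)
    volumes = {f"gantry_cyl_{i + 1}": cyl for i, cyl in enumerate(posed.gantry_cylinders)}
    volumes.update(posed.imaging_volumes)
    name = rng.choice(sorted(volumes))
    vol = volumes[name]
    if name.startswith("gantry_cyl"):
        u = vol.axis_direction
        t = rng.uniform(0.2, 0.8) * vol.length
        # random interior radial offset
        perp = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        inner = vol.axis_start + t * u + rng.uniform(0.0, 0.8) * vol.radius * perp
    else:
        # interior point of the prism via corner average with random weights
        w = rng.dirichlet(np.ones(8))
        inner = w @ vol.corners
    disp = posed.displacement
    from .geometry import couch_rotation_matrix

    home_point = couch_rotation_matrix(disp.rtn).T @ inner - np.array([-disp.lat, -disp.vrt, disp.lng])
    cloud = PointCloud(np.vstack([cloud.points, home_point]), label="phantom")
    return Scene(state, cloud, expected_collision=True, forced_volume=str(name),
                 margin=margin, seed=seed)


# ---------------------------------------------------------------------------
# export


def write_cloud_with_sidecar(cloud: PointCloud, spec: PhantomSpec, path, ground_truth: dict | None = None):
    """Write a cloud plus a JSON sidecar recording spec, seed, ground truth."""
    from .io import write_cloud

    path = Path(path)
    write_cloud(cloud, path)
    sidecar = {
        "spec": spec.metadata(),
        "n_points": len(cloud),
        "ground_truth": ground_truth or {},
    }
    Path(path.with_suffix(path.suffix + ".json")).write_text(json.dumps(sidecar, indent=2, default=float))
    return path
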