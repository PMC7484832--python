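"""Static linac / couch geometry, machine state, and posing.

The machine is described by a :class:`MachineGeometry` (static dimensions,
motion limits, readout conventions) and a :class:`MachineState` (the
posable degrees of freedom).  :func:`pose_machine` places every component
into the isocentric frame:

* the gantry head is a stack of four coaxial cylinders along the beam
  axis (vertical at gantry 0), bounded by five cap planes, rotated as a
  rigid body by the gantry rotation matrix;
* the MV imager and the kV source/imager arms are rectangular prisms
  rigidly attached to the gantry, each parameterized by a single
  extension ("vertical") distance from isocenter;
* the couch top is a trapezoidal prism, translated according to the
  LAT/LNG/VRT readouts and then rotated about the vertical isocenter
  axis by the couch rotation (RTN).

Couch home frame convention (readouts all zero / centered): the couch-top
surface lies in the ``x2 = 0`` plane, the couch centerline in ``x1 = 0``,
and the head (gantry-side) end of the couch top at ``x3 = 0``.  Readouts
map to displacements as

* LAT readout ``r``: couch centerline at ``x1 = -(lateral displacement)``
  where the displacement is ``lat_center_readout - r`` on the near-center
  branch and ``-r`` on the wrapped branch (readouts wrap at 0 /
  ``lat_center_readout``);
* VRT readout ``v``: couch top at ``x2 = -v`` (readout = drop of the top
  below isocenter);
* LNG readout ``l``: couch shifted ``+l`` cm along ``x3`` (readout =
  couch index distance, measured from the head end, of the point that
  sits at the isocenter plane).

The shipped default dimensions are PLACEHOLDERS on the scale of a modern
C-arm machine; real installations must load measured dimensions from a
config file (:func:`load_machine_geometry`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import yaml

from .geometry import (
    Cylinder,
    RectPrism,
    TrapezoidPrism,
    couch_rotation_matrix,
    gantry_rotation_matrix,
    normalize_angle,
)

__all__ = [
    "ConfigError",
    "MotionRangeError",
    "GantrySpec",
    "CouchSpec",
    "ImagerSpec",
    "MotionLimits",
    "MachineGeometry",
    "ImagerState",
    "MachineState",
    "CouchDisplacement",
    "PosedMachine",
    "default_geometry",
    "load_machine_geometry",
    "save_machine_geometry",
    "readout_to_iec",
    "iec_to_readout",
    "couch_transform",
    "pose_machine",
]


class ConfigError(ValueError):
    """Invalid or incomplete machine geometry configuration."""


class MotionRangeError(ValueError):
    """A requested machine state violates the configured motion limits."""


# ---------------------------------------------------------------------------
# static geometry


@dataclass(frozen=True)
class GantrySpec:
    """Gantry-head cylinder stack in the gantry-home frame.

    ``plane_offsets`` are the five cap-plane distances from isocenter
    along the beam axis (ascending); cylinder ``i`` spans planes ``i`` and
    ``i + 1`` with ``radii[i]``.  The lowest plane corresponds to the
    lowest point on the collimator face, so ``plane_offsets[0]`` is the
    isocenter-to-collimator clearance.
    """

    plane_offsets: tuple[float, ...] = (40.0, 52.0, 64.0, 76.0, 88.0)
    radii: tuple[float, ...] = (28.0, 33.0, 38.0, 45.0)

    def __post_init__(self):
        off = tuple(float(v) for v in self.plane_offsets)
        rad = tuple(float(v) for v in self.radii)
        object.__setattr__(self, "plane_offsets", off)
        object.__setattr__(self, "radii", rad)
        if len(off) != len(rad) + 1:
            raise ConfigError("gantry.plane_offsets must have one more entry than gantry.radii")
        if any(b <= a for a, b in zip(off, off[1:])):
            raise ConfigError("gantry.plane_offsets must be strictly ascending")
        if off[0] <= 0:
            raise ConfigError("gantry.plane_offsets[0] (isocenter clearance) must be positive")
        for i, r in enumerate(rad):
            if r <= 0:
                raise ConfigError(f"gantry.radii[{i}] must be positive, got {r}")


@dataclass(frozen=True)
class CouchSpec:
    """Couch-top trapezoidal prism dimensions (cm).

    The top tapers from ``width_foot`` at the foot end to ``width_head``
    at the head (gantry-side) end; ``thickness`` is the vertical depth of
    the prism below the top surface.
    """

    length: float = 230.0
    width_head: float = 47.0
    width_foot: float = 53.0
    thickness: float = 9.0

    def __post_init__(self):
        for key in ("length", "width_head", "width_foot", "thickness"):
            v = float(getattr(self, key))
            object.__setattr__(self, key, v)
            if v <= 0:
                raise ConfigError(f"couch.{key} must be positive, got {v}")


@dataclass(frozen=True)
class ImagerSpec:
    """Gantry-mounted device prism (MV imager, kV source, kV imager).

    ``direction`` is the unit vector (gantry at 0) from isocenter toward
    the device; the prism spans ``[vertical, vertical + thickness]`` along
    it, with cross-section ``width_a`` x ``width_b`` in the two
    perpendicular axes (for the MV imager: lateral x longitudinal; for
    the kV arms: vertical x longitudinal).
    """

    direction: tuple[float, float, float]
    thickness: float
    width_a: float
    width_b: float

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ConfigError("imager.direction must be nonzero")
        object.__setattr__(self, "direction", tuple(float(v) for v in d / n))
        for key in ("thickness", "width_a", "width_b"):
            v = float(getattr(self, key))
            object.__setattr__(self, key, v)
            if v <= 0:
                raise ConfigError(f"imager.{key} must be positive, got {v}")


@dataclass(frozen=True)
class MotionLimits:
    """Allowed ranges for each degree of freedom (cm / degrees).

    ``couch_lat`` limits the signed lateral displacement (not the wrapped
    readout); angular limits are on the signed internal scale.
    """

    couch_lat: tuple[float, float] = (-25.0, 25.0)
    couch_lng: tuple[float, float] = (0.0, 180.0)
    couch_vrt: tuple[float, float] = (-5.0, 60.0)
    couch_rtn: tuple[float, float] = (-95.0, 95.0)
    imager_vertical: tuple[float, float] = (20.0, 80.0)

    def __post_init__(self):
        for key in ("couch_lat", "couch_lng", "couch_vrt", "couch_rtn", "imager_vertical"):
            lo, hi = (float(v) for v in getattr(self, key))
            object.__setattr__(self, key, (lo, hi))
            if hi <= lo:
                raise ConfigError(f"limits.{key}: upper bound must exceed lower bound")

    def check(self, key: str, value: float) -> float:
        lo, hi = getattr(self, key)
        if not (lo <= value <= hi):
            raise MotionRangeError(f"{key}={value} outside allowed range [{lo}, {hi}]")
        return float(value)


def _default_imagers() -> dict[str, ImagerSpec]:
    return {
        "mv_imager": ImagerSpec(direction=(0.0, -1.0, 0.0), thickness=6.0, width_a=53.0, width_b=53.0),
        "kv_source": ImagerSpec(direction=(-1.0, 0.0, 0.0), thickness=30.0, width_a=25.0, width_b=25.0),
        "kv_imager": ImagerSpec(direction=(1.0, 0.0, 0.0), thickness=6.0, width_a=43.0, width_b=43.0),
    }


@dataclass(frozen=True)
class MachineGeometry:
    """Static machine dimensions, motion limits, and readout conventions.

    The default profile is a documented PLACEHOLDER (plausible C-arm
    proportions, not measurements of any specific machine); clinical use
    requires in-room measured dimensions supplied via config.
    """

    gantry: GantrySpec = field(default_factory=GantrySpec)
    couch: CouchSpec = field(default_factory=CouchSpec)
    mv_imager: ImagerSpec = None
    kv_source: ImagerSpec = None
    kv_imager: ImagerSpec = None
    limits: MotionLimits = field(default_factory=MotionLimits)
    lat_center_readout: float = 1000.0
    marker_lng_readout: float = 140.0
    marker_depth_below_top: float = 4.1

    def __post_init__(self):
        defaults = _default_imagers()
        for key in ("mv_imager", "kv_source", "kv_imager"):
            if getattr(self, key) is None:
                object.__setattr__(self, key, defaults[key])
        if self.lat_center_readout <= 0:
            raise ConfigError("lat_center_readout must be positive")
        if self.marker_depth_below_top <= 0:
            raise ConfigError("marker_depth_below_top must be positive")


def default_geometry() -> MachineGeometry:
    """The shipped placeholder machine profile (see class docstring)."""
    return MachineGeometry()


# ---------------------------------------------------------------------------
# config I/O


def _geometry_to_dict(geom: MachineGeometry) -> dict:
    d = asdict(geom)
    return d


def _build_imager(key: str, d: dict) -> ImagerSpec:
    try:
        return ImagerSpec(**d)
    except (TypeError, ConfigError) as exc:
        raise ConfigError(f"{key}: {exc}") from exc


def geometry_from_dict(d: dict) -> MachineGeometry:
    try:
        gantry = GantrySpec(**d.get("gantry", {}))
    except (TypeError, ConfigError) as exc:
        raise ConfigError(f"gantry: {exc}") from exc
    try:
        couch = CouchSpec(**d.get("couch", {}))
    except (TypeError, ConfigError) as exc:
        raise ConfigError(f"couch: {exc}") from exc
    try:
        limits = MotionLimits(**{k: tuple(v) for k, v in d.get("limits", {}).items()})
    except (TypeError, ConfigError) as exc:
        raise ConfigError(f"limits: {exc}") from exc
    defaults = _default_imagers()
    imagers = {}
    for key in ("mv_imager", "kv_source", "kv_imager"):
        imagers[key] = _build_imager(key, d[key]) if key in d else defaults[key]
    try:
        return MachineGeometry(
            gantry=gantry,
            couch=couch,
            limits=limits,
            lat_center_readout=float(d.get("lat_center_readout", 1000.0)),
            marker_lng_readout=float(d.get("marker_lng_readout", 140.0)),
            marker_depth_below_top=float(d.get("marker_depth_below_top", 4.1)),
            **imagers,
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_machine_geometry(source) -> MachineGeometry:
    """Load a machine geometry from a YAML/JSON file path or a dict."""
    if isinstance(source, MachineGeometry):
        return source
    if isinstance(source, dict):
        return geometry_from_dict(source)
    path = Path(source)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return geometry_from_dict(data)


def save_machine_geometry(geom: MachineGeometry, path) -> None:
    """Write a geometry config (YAML, or JSON for ``.json`` paths)."""
    path = Path(path)
    data = _geometry_to_dict(geom)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# machine state


@dataclass(frozen=True)
class ImagerState:
    deployed: bool = False
    vertical: float = 50.0


@dataclass(frozen=True)
class MachineState:
    """Posable degrees of freedom.

    Couch positions are machine-scale readouts (LAT wraps at
    ``lat_center_readout``); angles are degrees on [-360, 360] (displayed
    on the 0–360 IEC scale).  ``kv_arms`` deploys the kV source and kV
    imager together at a shared extension distance.
    """

    gantry_angle: float = 0.0
    couch_lat_readout: float = 1000.0
    couch_lng_readout: float = 100.0
    couch_vrt_readout: float = 20.0
    couch_rtn: float = 0.0
    mv_imager: ImagerState = field(default_factory=ImagerState)
    kv_arms: ImagerState = field(default_factory=ImagerState)

    def with_(self, **kwargs) -> "MachineState":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CouchDisplacement:
    """Couch position in IEC displacements (cm) plus rotation (degrees).

    ``lat`` is the signed lateral offset in the readout-formula sense: the
    lateral distance of the aligned point from the couch centerline, so a
    readout just below ``lat_center_readout`` gives a small positive
    value and a small positive readout gives a negative value.
    """

    lat: float
    lng: float
    vrt: float
    rtn: float


def readout_to_iec(state: MachineState, geom: MachineGeometry) -> CouchDisplacement:
    """Convert machine readouts to IEC displacements, enforcing limits.

    Inverts the wrapped lateral readout mapping (readouts near
    ``lat_center_readout`` are positive displacements, readouts just above
    zero are negative); LNG and VRT are linear in their readouts.
    """
    center = geom.lat_center_readout
    r = float(state.couch_lat_readout)
    if not (0.0 <= r <= center):
        raise MotionRangeError(f"couch_lat_readout={r} outside [0, {center}]")
    lat = center - r if r > center / 2.0 else -r
    lat = geom.limits.check("couch_lat", lat)
    lng = geom.limits.check("couch_lng", float(state.couch_lng_readout))
    vrt = geom.limits.check("couch_vrt", float(state.couch_vrt_readout))
    rtn = geom.limits.check("couch_rtn", normalize_angle(state.couch_rtn))
    return CouchDisplacement(lat=lat, lng=lng, vrt=vrt, rtn=rtn)


def iec_to_readout(disp: CouchDisplacement, geom: MachineGeometry) -> MachineState:
    """Inverse of :func:`readout_to_iec` on the couch axes."""
    center = geom.lat_center_readout
    lat_readout = center - disp.lat if disp.lat >= 0 else -disp.lat
    if disp.lat == 0:
        lat_readout = center
    return MachineState(
        couch_lat_readout=lat_readout,
        couch_lng_readout=disp.lng,
        couch_vrt_readout=disp.vrt,
        couch_rtn=disp.rtn,
    )


# ---------------------------------------------------------------------------
# posing


def couch_transform(points: np.ndarray, disp: CouchDisplacement) -> np.ndarray:
    """Pose couch-home-frame points: translate per readouts, then rotate RTN.

    The same transform is applied to the couch prism, the densified couch
    surface points, and any patient cloud riding on the couch.  The
    rotation is about the vertical axis through the isocenter, so a point
    placed at the isocenter is invariant under pure RTN changes.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts).astype(float)
    shifted = pts + np.array([-disp.lat, -disp.vrt, disp.lng])
    out = shifted @ couch_rotation_matrix(disp.rtn).T
    return out[0] if single else out


def _couch_home_corners(couch: CouchSpec) -> np.ndarray:
    """8 corners of the couch-top prism in the couch home frame."""
    wh, wf = couch.width_head / 2.0, couch.width_foot / 2.0
    L, t = couch.length, couch.thickness
    bottom = np.array(
        [[-wf, -t, -L], [wf, -t, -L], [wh, -t, 0.0], [-wh, -t, 0.0]]
    )
    top = bottom + np.array([0.0, t, 0.0])
    return np.vstack([bottom, top])


def _sample_quad(quad: np.ndarray, step: float) -> np.ndarray:
    """Grid-sample a planar quad (corner loop) at <= ``step`` spacing."""
    p0, p1, p2, p3 = quad
    nu = max(int(np.ceil(max(np.linalg.norm(p1 - p0), np.linalg.norm(p2 - p3)) / step)), 1) + 1
    nv = max(int(np.ceil(max(np.linalg.norm(p3 - p0), np.linalg.norm(p2 - p1)) / step)), 1) + 1
    u = np.linspace(0.0, 1.0, nu)
    v = np.linspace(0.0, 1.0, nv)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    uu = uu.ravel()[:, None]
    vv = vv.ravel()[:, None]
    # bilinear patch; planar quads stay exactly on the face plane
    return (
        (1 - uu) * (1 - vv) * p0
        + uu * (1 - vv) * p1
        + uu * vv * p2
        + (1 - uu) * vv * p3
    )


from functools import lru_cache


@lru_cache(maxsize=8)
def _home_surface_cached(couch: CouchSpec, step: float) -> np.ndarray:
    """Densified couch-top surface in the home frame (shared across poses)."""
    pts = _sample_prism_surface(_couch_home_corners(couch), step)
    pts.setflags(write=False)
    return pts


def _sample_prism_surface(corners: np.ndarray, step: float) -> np.ndarray:
    faces = (
        (0, 1, 2, 3),
        (4, 5, 6, 7),
        (0, 1, 5, 4),
        (1, 2, 6, 5),
        (2, 3, 7, 6),
        (3, 0, 4, 7),
    )
    parts = [_sample_quad(corners[list(f)], step) for f in faces]
    return np.vstack(parts)


def _imager_home_corners(spec: ImagerSpec, vertical: float) -> np.ndarray:
    d = np.asarray(spec.direction, dtype=float)
    # perpendicular axes: width_a along the first non-parallel canonical
    # axis pair (vertical devices: lateral/longitudinal; lateral devices:
    # vertical/longitudinal)
    if abs(d[1]) > 0.9:
        a_axis = np.array([1.0, 0.0, 0.0])
    else:
        a_axis = np.array([0.0, 1.0, 0.0])
    b_axis = np.cross(d, a_axis)
    b_axis /= np.linalg.norm(b_axis)
    a_axis = np.cross(b_axis, d)
    near = d * vertical
    far = d * (vertical + spec.thickness)
    ha, hb = spec.width_a / 2.0, spec.width_b / 2.0
    loop = [(-ha, -hb), (ha, -hb), (ha, hb), (-ha, hb)]
    bottom = np.array([near + a * a_axis + b * b_axis for a, b in loop])
    top = np.array([far + a * a_axis + b * b_axis for a, b in loop])
    return np.vstack([bottom, top])


@dataclass(frozen=True)
class PosedMachine:
    """All machine volumes posed into the isocentric frame for one state."""

    gantry_cylinders: tuple[Cylinder, ...]
    gantry_axis: np.ndarray  # unit beam-axis direction (isocenter -> source)
    imaging_volumes: dict  # name -> RectPrism, deployed devices only
    couch_volume: TrapezoidPrism
    couch_surface_points: np.ndarray
    displacement: CouchDisplacement
    state: MachineState

    @property
    def gantry_plane_offsets(self) -> np.ndarray:
        """Cap-plane distances from isocenter along the posed beam axis."""
        c0 = self.gantry_cylinders[0]
        offs = [float(c0.axis_start @ self.gantry_axis)]
        for cyl in self.gantry_cylinders:
            offs.append(float(cyl.axis_end @ self.gantry_axis))
        return np.array(offs)

    @property
    def gantry_radii(self) -> np.ndarray:
        return np.array([c.radius for c in self.gantry_cylinders])

    def longitudinal_bounds(self, guard: float = 0.0) -> tuple[float, float]:
        """Inferior/superior ``x3`` extent of gantry + deployed devices."""
        lo, hi = np.inf, -np.inf
        for cyl in self.gantry_cylinders:
            for p in (cyl.axis_start, cyl.axis_end):
                lo = min(lo, p[2] - cyl.radius)
                hi = max(hi, p[2] + cyl.radius)
        for prism in self.imaging_volumes.values():
            lo = min(lo, prism.corners[:, 2].min())
            hi = max(hi, prism.corners[:, 2].max())
        return lo - guard, hi + guard


def pose_machine(geom: MachineGeometry, state: MachineState, sampling: float = 1.0) -> PosedMachine:
    """Pose every component for ``state``; validates motion limits.

    ``sampling`` is the maximum spacing (cm) of the densified couch-top
    surface points used as collision test points.
    """
    if sampling <= 0:
        raise ValueError("sampling step must be positive")
    disp = readout_to_iec(state, geom)
    R = gantry_rotation_matrix(state.gantry_angle)
    axis_home = np.array([0.0, 1.0, 0.0])
    axis = R @ axis_home

    cylinders = []
    offs = geom.gantry.plane_offsets
    for i, r in enumerate(geom.gantry.radii):
        s = R @ (axis_home * offs[i])
        e = R @ (axis_home * offs[i + 1])
        cylinders.append(Cylinder(axis_start=s, axis_end=e, radius=r))

    imaging = {}
    if state.mv_imager.deployed:
        v = geom.limits.check("imager_vertical", state.mv_imager.vertical)
        imaging["mv_imager"] = RectPrism(_imager_home_corners(geom.mv_imager, v) @ R.T)
    if state.kv_arms.deployed:
        v = geom.limits.check("imager_vertical", state.kv_arms.vertical)
        imaging["kv_source"] = RectPrism(_imager_home_corners(geom.kv_source, v) @ R.T)
        imaging["kv_imager"] = RectPrism(_imager_home_corners(geom.kv_imager, v) @ R.T)

    home_corners = _couch_home_corners(geom.couch)
    posed_corners = couch_transform(home_corners, disp)
    couch_volume = TrapezoidPrism(posed_corners)
    surface = couch_transform(_home_surface_cached(geom.couch, float(sampling)), disp)

    return PosedMachine(
        gantry_cylinders=tuple(cylinders),
        gantry_axis=axis,
        imaging_volumes=imaging,
        couch_volume=couch_volume,
        couch_surface_points=surface,
        displacement=disp,
        state=state,
    )
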