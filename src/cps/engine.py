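"""Collision detection, boundary sweeps, clearance maps, plan verification.

The engine answers one question — does any test point sit inside any
machine volume? — for a machine state and a patient cloud.  Test points
are the densified couch-top surface plus the patient cloud (given in the
couch home frame; the engine applies the couch translations and rotation
to the patient identically to the couch itself).  Test volumes are the
four gantry-head cylinders, tested with the plane-pair routing over the
five cap planes, and each deployed imaging prism, tested with six face
dot products.  Verdicts are boundary-inclusive and monotone in the
optional isotropic ``margin``, which inflates every volume.

A longitudinal pre-filter discards test points outside the
superior/inferior extent of the gantry head and deployed devices
(plus a guard band) before containment testing; it is a pure speed-up
and never changes a verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import ON_PLANE_TOL, normalize_angle, to_iec_scale
from .machine import (
    MachineGeometry,
    MachineState,
    PosedMachine,
    couch_transform,
    pose_machine,
    readout_to_iec,
)
from .patient import PointCloud

__all__ = [
    "SweepError",
    "PlanFormatError",
    "CollisionReport",
    "SweepResult",
    "ClearanceMap",
    "prefilter_points",
    "detect_collision",
    "sweep_boundary",
    "clearance_map",
    "verify_plan",
]

#: default sweep steps: 0.1 cm for translations, 0.25 deg for rotations
DEFAULT_LAT_STEP = 0.1
DEFAULT_RTN_STEP = 0.25
#: default longitudinal guard band for the pre-filter, cm
DEFAULT_GUARD = 1.0


class SweepError(RuntimeError):
    """A boundary sweep could not start (initial state already collides)."""


class PlanFormatError(ValueError):
    """A control point in a plan could not be interpreted."""


@dataclass(frozen=True)
class CollisionReport:
    """Verdict for one machine state.

    ``pairs`` lists every (moving structure, machine volume) combination
    with at least one contained test point; ``offending_points`` is a
    capped subsample of the colliding points (isocentric frame).
    """

    collided: bool
    pairs: tuple[tuple[str, str], ...]
    offending_points: np.ndarray
    state: MachineState

    def __post_init__(self):
        if self.collided != bool(self.pairs):
            raise ValueError("collided flag must match pair list")


@dataclass(frozen=True)
class SweepResult:
    axis: str
    last_clear: float
    first_collide: float | None
    clear_to_limit: bool
    report: CollisionReport | None
    step: float


# ---------------------------------------------------------------------------
# core point-vs-volume tests


def _gantry_routing_test(points: np.ndarray, posed: PosedMachine, margin: float) -> np.ndarray:
    """Per-point, per-cylinder membership matrix for the gantry stack.

    Routing: points are first gated between the outermost cap planes
    (planes 1 and 5); only gated points are assigned to plane pairs by
    their axial coordinate and compared against the matching radius.
    A point within ``margin`` of a shared cap plane lies inside both
    adjacent inflated cylinders, so membership is a matrix rather than a
    single index — exactly equivalent to testing each (inflated)
    cylinder independently.
    """
    a = posed.gantry_axis
    offs = posed.gantry_plane_offsets
    radii = posed.gantry_radii
    t = points @ a
    radial = np.linalg.norm(points - t[:, None] * a[None, :], axis=1)

    hit = np.zeros((len(points), len(radii)), dtype=bool)
    gate = (t >= offs[0] - margin - ON_PLANE_TOL) & (t <= offs[-1] + margin + ON_PLANE_TOL)
    if not np.any(gate):
        return hit
    tg = t[gate]
    rg = radial[gate]
    sub = np.zeros((len(tg), len(radii)), dtype=bool)
    for k, r in enumerate(radii):
        in_slab = (tg >= offs[k] - margin - ON_PLANE_TOL) & (tg <= offs[k + 1] + margin + ON_PLANE_TOL)
        sub[:, k] = in_slab & (rg <= r + margin + ON_PLANE_TOL)
    hit[np.where(gate)[0]] = sub
    return hit


def _test_points(posed: PosedMachine, points: np.ndarray, sources: np.ndarray,
                 margin: float, guard: float, max_offending: int):
    """Run all containment tests; return (pairs, offending points)."""
    pairs: list[tuple[str, str]] = []
    offending: list[np.ndarray] = []
    if len(points) == 0:
        return pairs, np.empty((0, 3))

    lo, hi = posed.longitudinal_bounds(guard=guard + margin)
    keep = (points[:, 2] >= lo) & (points[:, 2] <= hi)
    pts = points[keep]
    srcs = sources[keep]
    if len(pts) == 0:
        return pairs, np.empty((0, 3))

    hit_any = np.zeros(len(pts), dtype=bool)
    gantry_hit = _gantry_routing_test(pts, posed, margin)
    for k in range(len(posed.gantry_cylinders)):
        mask = gantry_hit[:, k]
        if np.any(mask):
            hit_any |= mask
            for src in np.unique(srcs[mask]):
                pairs.append((str(src), f"gantry_cyl_{k + 1}"))

    for name, prism in posed.imaging_volumes.items():
        mask = prism.contains(pts, margin=margin)
        if np.any(mask):
            hit_any |= mask
            for src in np.unique(srcs[mask]):
                pairs.append((str(src), name))

    if np.any(hit_any):
        offending.append(pts[hit_any][:max_offending])
    off = np.vstack(offending) if offending else np.empty((0, 3))
    return sorted(set(pairs)), off


def _assemble_points(posed: PosedMachine, patient: PointCloud | None):
    points = [posed.couch_surface_points]
    sources = [np.full(len(posed.couch_surface_points), "couch", dtype=object)]
    if patient is not None and len(patient):
        posed_patient = couch_transform(patient.points, posed.displacement)
        points.append(posed_patient)
        sources.append(np.full(len(posed_patient), "patient", dtype=object))
    return np.vstack(points), np.concatenate(sources)


def prefilter_points(cloud: PointCloud, posed: PosedMachine, guard: float = DEFAULT_GUARD) -> PointCloud:
    """Keep only points within the gantry/device longitudinal range.

    Retains every point between the inferior and superior bounding
    planes of the posed gantry head and deployed devices, extended by
    ``guard`` cm.  Sound by construction: no containment test can flag a
    point outside those bounds.
    """
    lo, hi = posed.longitudinal_bounds(guard=guard)
    mask = (cloud.points[:, 2] >= lo) & (cloud.points[:, 2] <= hi)
    labels = cloud.point_labels[mask] if cloud.point_labels is not None else None
    return PointCloud(cloud.points[mask], label=cloud.label, point_labels=labels)


def detect_collision(
    geom: MachineGeometry,
    state: MachineState,
    patient: PointCloud | None = None,
    margin: float = 0.0,
    sampling: float = 1.0,
    guard: float = DEFAULT_GUARD,
    max_offending: int = 200,
) -> CollisionReport:
    """Collision verdict for one machine state.

    ``patient`` is given in the couch home frame (it rides with the
    couch).  ``margin`` inflates every machine volume isotropically (cm)
    on top of the already conservative geometry.  Deterministic: the same
    inputs always produce the same report.
    """
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    posed = pose_machine(geom, state, sampling=sampling)
    points, sources = _assemble_points(posed, patient)
    pairs, offending = _test_points(posed, points, sources, margin, guard, max_offending)
    return CollisionReport(
        collided=bool(pairs),
        pairs=tuple(pairs),
        offending_points=offending,
        state=state,
    )


# ---------------------------------------------------------------------------
# boundary sweeps


def _advance_state(state: MachineState, axis: str, value: float, geom: MachineGeometry) -> MachineState:
    if axis == "couch_lat":
        # sweep in displacement space to avoid the readout wrap; store as readout
        center = geom.lat_center_readout
        readout = center - value if value >= 0 else -value
        return state.with_(couch_lat_readout=readout)
    if axis == "couch_rtn":
        return state.with_(couch_rtn=value)
    raise ValueError(f"unsupported sweep axis {axis!r}")


def _axis_value(state: MachineState, axis: str, geom: MachineGeometry) -> float:
    disp = readout_to_iec(state, geom)
    return disp.lat if axis == "couch_lat" else disp.rtn


def _axis_limits(axis: str, geom: MachineGeometry) -> tuple[float, float]:
    return geom.limits.couch_lat if axis == "couch_lat" else geom.limits.couch_rtn


def _axis_readout(axis: str, value: float, geom: MachineGeometry) -> float:
    if axis == "couch_lat":
        center = geom.lat_center_readout
        return center - value if value >= 0 else -value
    return value


def sweep_boundary(
    geom: MachineGeometry,
    state: MachineState,
    patient: PointCloud | None = None,
    axis: str = "couch_lat",
    direction: int = 1,
    step: float | None = None,
    margin: float = 0.0,
    sampling: float = 1.0,
) -> SweepResult:
    """Advance one couch axis until the first collision.

    Mirrors the in-room procedure: starting from a collision-free state,
    the couch is stepped along ``axis`` (lateral displacement in cm or
    rotation in degrees, sign per ``direction``) until a collision is
    detected.  Returns the last collision-free readout and the first
    colliding readout (exactly one step apart), or ``clear_to_limit``
    when the motion limit is reached first.  A linear sweep guarantees
    the first collision along the path is found even when the clear
    region is non-convex.
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    if step is None:
        step = DEFAULT_LAT_STEP if axis == "couch_lat" else DEFAULT_RTN_STEP
    if step <= 0:
        raise ValueError("step must be positive")

    start = detect_collision(geom, state, patient, margin=margin, sampling=sampling)
    if start.collided:
        raise SweepError(f"starting state already collides: {start.pairs}")

    lo, hi = _axis_limits(axis, geom)
    start = _axis_value(state, axis, geom)
    value = start
    k = 0
    while True:
        k += 1
        nxt = start + k * direction * step
        # snap values within rounding error of a limit onto the limit
        if abs(nxt - lo) < 1e-9:
            nxt = lo
        elif abs(nxt - hi) < 1e-9:
            nxt = hi
        if nxt < lo or nxt > hi:
            return SweepResult(
                axis=axis,
                last_clear=_axis_readout(axis, value, geom),
                first_collide=None,
                clear_to_limit=True,
                report=None,
                step=step,
            )
        candidate = _advance_state(state, axis, nxt, geom)
        report = detect_collision(geom, candidate, patient, margin=margin, sampling=sampling)
        if report.collided:
            return SweepResult(
                axis=axis,
                last_clear=_axis_readout(axis, value, geom),
                first_collide=_axis_readout(axis, nxt, geom),
                clear_to_limit=False,
                report=report,
                step=step,
            )
        value = nxt


# ---------------------------------------------------------------------------
# clearance maps


@dataclass(frozen=True)
class ClearanceMap:
    """Boolean collision-free grid over (couch rotation x gantry angle).

    ``clear[i, j]`` is True when the state with ``couch_rtn_grid[i]`` and
    ``gantry_grid[j]`` (other axes from ``fixed_state``) is collision
    free.  Gantry angles are stored on the 0-360 display scale.
    """

    couch_rtn_grid: np.ndarray
    gantry_grid: np.ndarray
    clear: np.ndarray
    fixed_state: MachineState

    def __post_init__(self):
        rtn = np.asarray(self.couch_rtn_grid, dtype=float)
        g = np.asarray(self.gantry_grid, dtype=float)
        c = np.asarray(self.clear, dtype=bool)
        if c.shape != (len(rtn), len(g)):
            raise ValueError("clear matrix shape must be (len(rtn_grid), len(gantry_grid))")
        object.__setattr__(self, "couch_rtn_grid", rtn)
        object.__setattr__(self, "gantry_grid", g)
        object.__setattr__(self, "clear", c)

    @property
    def clear_fraction(self) -> float:
        return float(self.clear.mean())

    def to_csv(self, path) -> None:
        """Header row = gantry grid, first column = couch rotation, cells 0/1."""
        path = Path(path)
        header = "rtn\\gantry," + ",".join(f"{g:g}" for g in self.gantry_grid)
        lines = [header]
        for r, row in zip(self.couch_rtn_grid, self.clear.astype(int)):
            lines.append(f"{r:g}," + ",".join(str(v) for v in row))
        path.write_text("\n".join(lines) + "\n")

    def plot(self, path=None, ax=None):
        """Render the map (clear = light, collision = dark)."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4.5))
        extent = [
            self.gantry_grid[0],
            self.gantry_grid[-1],
            self.couch_rtn_grid[0],
            self.couch_rtn_grid[-1],
        ]
        ax.imshow(
            self.clear,
            origin="lower",
            aspect="auto",
            extent=extent,
            cmap="RdYlGn",
            vmin=0,
            vmax=1,
            interpolation="nearest",
        )
        ax.set_xlabel("gantry angle (deg)")
        ax.set_ylabel("couch rotation (deg)")
        ax.set_title("collision-free space")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def clearance_map(
    geom: MachineGeometry,
    fixed_state: MachineState,
    patient: PointCloud | None,
    rtn_grid,
    gantry_grid,
    margin: float = 0.0,
    sampling: float = 1.0,
) -> ClearanceMap:
    """Evaluate the collision verdict on a (couch rtn x gantry angle) grid.

    Toggling deployed imaging devices in ``fixed_state`` turns the same
    map into an imaging-angle availability chart.
    """
    rtn_grid = np.asarray(rtn_grid, dtype=float)
    gantry_grid = np.asarray(gantry_grid, dtype=float)
    if rtn_grid.size == 0 or gantry_grid.size == 0:
        raise ValueError("grids must be nonempty")
    clear = np.empty((len(rtn_grid), len(gantry_grid)), dtype=bool)
    for i, rtn in enumerate(rtn_grid):
        for j, g in enumerate(gantry_grid):
            state = fixed_state.with_(couch_rtn=normalize_angle(rtn), gantry_angle=normalize_angle(g))
            report = detect_collision(geom, state, patient, margin=margin, sampling=sampling)
            clear[i, j] = not report.collided
    display_gantry = np.array([to_iec_scale(g) for g in gantry_grid])
    return ClearanceMap(
        couch_rtn_grid=rtn_grid,
        gantry_grid=display_gantry,
        clear=clear,
        fixed_state=fixed_state,
    )


# ---------------------------------------------------------------------------
# plan verification


def verify_plan(
    geom: MachineGeometry,
    fixed_state: MachineState,
    patient: PointCloud | None,
    control_points,
    margin: float = 0.0,
    sampling: float = 1.0,
) -> list[CollisionReport]:
    """Per-control-point collision verdicts; pass iff all are clear.

    Each control point is a mapping with any of the keys ``gantry``,
    ``rtn``, ``lat``, ``lng``, ``vrt`` (readout values); unspecified axes
    come from ``fixed_state``.
    """
    control_points = list(control_points)
    if not control_points:
        raise PlanFormatError("control point list is empty")
    keymap = {
        "gantry": "gantry_angle",
        "rtn": "couch_rtn",
        "lat": "couch_lat_readout",
        "lng": "couch_lng_readout",
        "vrt": "couch_vrt_readout",
    }
    reports = []
    for i, cp in enumerate(control_points):
        if not isinstance(cp, dict):
            raise PlanFormatError(f"control point {i}: expected a mapping, got {type(cp).__name__}")
        unknown = set(cp) - set(keymap)
        if unknown:
            raise PlanFormatError(f"control point {i}: unknown keys {sorted(unknown)}")
        try:
            kwargs = {keymap[k]: float(v) for k, v in cp.items()}
        except (TypeError, ValueError) as exc:
            raise PlanFormatError(f"control point {i}: {exc}") from exc
        state = fixed_state.with_(**kwargs)
        reports.append(detect_collision(geom, state, patient, margin=margin, sampling=sampling))
    return reports
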