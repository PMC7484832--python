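"""Independent reference implementations used to cross-check the engine.

Everything here deliberately avoids the code paths of the package under
test: prism containment goes through a Delaunay tessellation of the
corner set, cylinder containment through the cross-product distance to
the axis line, and the full-scene verdict through a flat loop over every
point and every volume with no pre-filter and no plane-pair routing.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay

from cps.geometry import couch_rotation_matrix
from cps.machine import pose_machine


def cylinder_contains_oracle(points, axis_start, axis_end, radius, margin=0.0, tol=1e-9):
    """Cylinder containment via |cross| distance, written independently."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    s = np.asarray(axis_start, dtype=float)
    e = np.asarray(axis_end, dtype=float)
    axis = e - s
    length = np.linalg.norm(axis)
    u = axis / length
    t = (p - s) @ u
    d = np.linalg.norm(np.cross(p - s, u), axis=1)
    return (t >= -margin - tol) & (t <= length + margin + tol) & (d <= radius + margin + tol)


def prism_contains_oracle(points, corners, margin=0.0, tol=1e-9):
    """Prism containment via Delaunay tessellation of the (inflated) hull.

    Margin inflation is applied by pushing each corner away from the
    centroid along its three incident face normals' resultant; for the
    axis-aligned-constructed prisms used in these tests an exact
    halfspace-offset check is also applied for points near the surface.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    c = np.asarray(corners, dtype=float)
    if margin == 0.0:
        hull = Delaunay(c)
        inside = hull.find_simplex(p) >= 0
        # Delaunay's own eps differs from the boundary-inclusive rule;
        # re-check near-boundary points with exact plane offsets
        near = ~inside
        if np.any(near):
            inside[near] = _halfspace_oracle(p[near], c, 0.0, tol)
        return inside
    return _halfspace_oracle(p, c, margin, tol)


def _halfspace_oracle(p, corners, margin, tol):
    """All-faces halfspace test derived from the convex hull facets."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(corners)
    # hull equations: n . x + b <= 0 inside
    eq = hull.equations
    vals = p @ eq[:, :3].T + eq[:, 3][None, :]
    return np.all(vals <= margin + tol, axis=1)


def brute_force_verdict(geom, state, patient_points_home, margin=0.0, sampling=1.0):
    """Scene verdict: every test point against every volume, no shortcuts.

    Patient points (couch home frame) are posed with explicit matrix
    algebra; couch surface points are taken from the posed machine
    (the densification itself is shared plumbing, not under test).
    """
    posed = pose_machine(geom, state, sampling=sampling)
    pts = [posed.couch_surface_points]
    if patient_points_home is not None and len(patient_points_home):
        shift = np.array([-posed.displacement.lat, -posed.displacement.vrt, posed.displacement.lng])
        moved = (np.asarray(patient_points_home, dtype=float) + shift) @ couch_rotation_matrix(
            posed.displacement.rtn
        ).T
        pts.append(moved)
    pts = np.vstack(pts)

    hits = set()
    for i, cyl in enumerate(posed.gantry_cylinders):
        if np.any(cylinder_contains_oracle(pts, cyl.axis_start, cyl.axis_end, cyl.radius, margin)):
            hits.add(f"gantry_cyl_{i + 1}")
    for name, prism in posed.imaging_volumes.items():
        if np.any(prism_contains_oracle(pts, prism.corners, margin)):
            hits.add(name)
    return bool(hits), hits
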