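"""Treatment-couch coordinate prediction from the isocenter selection.

A radio-opaque reference marker embedded under the CT couch top
establishes the correspondence between the CT couch and the linac couch:
the marker is laterally centered, sits a known depth below the couch-top
surface (default 4.1 cm), and corresponds to a known linac couch
longitude readout (default 140).  Given the treatment isocenter
``(X, Y, Z)`` and the marker ``(X*, Y*, Z*)`` in CT image coordinates
(x lateral, y down for a supine patient, z superior), the couch readouts
are

* ``LAT = C - (X - X*)`` when ``X > X*`` and ``-(X - X*)`` when
  ``X < X*`` (``C`` is the centered readout, default 1000; readouts wrap
  at 0/``C``),
* ``VRT = Y* - Y - depth`` (the height of the isocenter above the couch
  top),
* ``LNG = L* - (Z - Z*)`` with ``L*`` the marker longitude readout.

The method assumes identical couch indexing between the CT and linac
couches; clinic-specific constants are configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import as_point, as_points

__all__ = [
    "IsocenterSelection",
    "MarkerCorrespondence",
    "CouchReadouts",
    "predict_lat",
    "predict_vrt",
    "predict_lng",
    "predict_couch",
    "ct_to_couch_frame",
]


@dataclass(frozen=True)
class IsocenterSelection:
    """Treatment isocenter in CT image coordinates (cm)."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        as_point((self.x, self.y, self.z))


@dataclass(frozen=True)
class MarkerCorrespondence:
    """CT position of the couch reference marker and readout constants."""

    marker_x: float
    marker_y: float
    marker_z: float
    depth_below_top: float = 4.1
    marker_lng_readout: float = 140.0
    lat_center_readout: float = 1000.0

    def __post_init__(self):
        as_point((self.marker_x, self.marker_y, self.marker_z))
        if self.depth_below_top <= 0:
            raise ValueError("depth_below_top must be positive")


@dataclass(frozen=True)
class CouchReadouts:
    lat: float
    vrt: float
    lng: float


def predict_lat(iso: IsocenterSelection, m: MarkerCorrespondence) -> float:
    """Wrapped lateral readout; ``X == X*`` returns the centered readout."""
    dx = iso.x - m.marker_x
    if dx > 0:
        return m.lat_center_readout - dx
    if dx < 0:
        return -dx
    return m.lat_center_readout


def predict_vrt(iso: IsocenterSelection, m: MarkerCorrespondence) -> float:
    """Vertical readout: isocenter height above the couch-top surface."""
    return m.marker_y - iso.y - m.depth_below_top


def predict_lng(iso: IsocenterSelection, m: MarkerCorrespondence) -> float:
    """Longitude readout relative to the marker's known couch index."""
    return m.marker_lng_readout - (iso.z - m.marker_z)


def predict_couch(iso: IsocenterSelection, m: MarkerCorrespondence) -> CouchReadouts:
    """All three couch readouts for one isocenter selection.

    Feeding the result through the machine readout conversion and couch
    posing places the selected isocenter at the machine origin.
    """
    return CouchReadouts(
        lat=predict_lat(iso, m),
        vrt=predict_vrt(iso, m),
        lng=predict_lng(iso, m),
    )


def ct_to_couch_frame(points, m: MarkerCorrespondence):
    """Map CT-image coordinates to the couch home frame.

    Couch home frame: centerline at ``x1 = 0``, couch-top surface at
    ``x2 = 0``, head (gantry-side) end at ``x3 = 0``.  The marker defines
    the mapping: laterally centered, ``depth_below_top`` under the top
    surface, at couch index ``marker_lng_readout`` from the head end.
    CT y points down, so height above the couch top is
    ``(Y* - depth) - y``.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    p = as_points(pts)
    x1 = p[:, 0] - m.marker_x
    x2 = (m.marker_y - m.depth_below_top) - p[:, 1]
    x3 = (p[:, 2] - m.marker_z) - m.marker_lng_readout
    out = np.column_stack([x1, x2, x3])
    return out[0] if single else out
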