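"""Point-cloud and DICOM input/output.

Clouds are exchanged as plain-text XYZ (whitespace-delimited), ASCII PLY,
or CSV with an ``x,y,z`` header.  CT structures come from DICOM
RT-STRUCT files (body contour extraction); the plan isocenter can be
read from DICOM RT-PLAN.  DICOM distances are millimetres and are
converted to the cm used everywhere in this package.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .patient import PointCloud, contours_to_cloud

__all__ = [
    "read_cloud",
    "write_cloud",
    "read_rtstruct_cloud",
    "read_rtplan_isocenter",
]

_BODY_NAMES = ("body", "external", "skin", "outer contour")


def _read_xyz(path: Path) -> np.ndarray:
    return np.loadtxt(path, dtype=float, ndmin=2)


def _read_csv(path: Path) -> np.ndarray:
    return np.loadtxt(path, dtype=float, delimiter=",", skiprows=1, ndmin=2)


def _read_ply(path: Path) -> np.ndarray:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    n = None
    fmt_ok = False
    end = None
    for i, line in enumerate(lines[1:], start=1):
        tokens = line.split()
        if tokens[:2] == ["format", "ascii"]:
            fmt_ok = True
        elif tokens[:2] == ["element", "vertex"]:
            n = int(tokens[2])
        elif tokens[:1] == ["end_header"]:
            end = i
            break
    if not fmt_ok:
        raise ValueError(f"{path}: only ascii PLY is supported")
    if n is None or end is None:
        raise ValueError(f"{path}: malformed PLY header")
    data = [list(map(float, lines[end + 1 + k].split()[:3])) for k in range(n)]
    return np.asarray(data, dtype=float).reshape(n, 3)


def read_cloud(path, label: str | None = None) -> PointCloud:
    """Read a point cloud from ``.xyz``/``.txt``, ``.csv`` or ``.ply``."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        pts = _read_ply(path)
    elif suffix == ".csv":
        pts = _read_csv(path)
    else:
        pts = _read_xyz(path)
    if pts.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 coordinate columns")
    return PointCloud(pts[:, :3], label=label or path.stem)


def write_cloud(cloud: PointCloud, path) -> None:
    """Write a cloud in the format implied by the path suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    pts = cloud.points
    if suffix == ".ply":
        header = [
            "ply",
            "format ascii 1.0",
            f"element vertex {len(pts)}",
            "property float x",
            "property float y",
            "property float z",
            "end_header",
        ]
        body = [" ".join(f"{v:.6f}" for v in p) for p in pts]
        path.write_text("\n".join(header + body) + "\n")
    elif suffix == ".csv":
        np.savetxt(path, pts, delimiter=",", header="x,y,z", comments="", fmt="%.6f")
    else:
        np.savetxt(path, pts, fmt="%.6f")


# ---------------------------------------------------------------------------
# DICOM


def _load_dataset(source):
    import pydicom

    if isinstance(source, pydicom.dataset.Dataset):
        return source
    return pydicom.dcmread(str(source), force=True)


def read_rtstruct_cloud(source, roi_name: str | None = None, step: float | None = None) -> PointCloud:
    """Extract a structure's contour points from a DICOM RT-STRUCT.

    With ``roi_name`` unset, the first ROI whose name matches a common
    body/external alias is used.  Contour data (mm, per closed planar
    polygon) is converted to cm and kept in CT image coordinates
    (x lateral, y posterior/down for a supine patient, z superior) — the
    same frame the couch-prediction formulas and the CT-to-couch mapping
    expect.
    """
    ds = _load_dataset(source)
    rois = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    target_number = None
    if roi_name is not None:
        for num, name in rois.items():
            if name.lower() == roi_name.lower():
                target_number = num
                break
        if target_number is None:
            raise ValueError(f"ROI {roi_name!r} not found; available: {sorted(rois.values())}")
    else:
        for num, name in rois.items():
            if name.lower() in _BODY_NAMES:
                target_number = num
                break
        if target_number is None:
            raise ValueError(f"no body/external ROI found; available: {sorted(rois.values())}")

    slices = []
    for roi_contour in ds.ROIContourSequence:
        if int(roi_contour.ReferencedROINumber) != target_number:
            continue
        for contour in getattr(roi_contour, "ContourSequence", []):
            data = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3) / 10.0
            z = float(np.mean(data[:, 2]))
            slices.append((z, data[:, :2]))
    if not slices:
        raise ValueError(f"ROI {rois[target_number]!r} has no contour data")
    return contours_to_cloud(slices, step=step, label="ct_contour")


def read_rtplan_isocenter(source) -> np.ndarray:
    """Read the first beam isocenter position (cm) from a DICOM RT-PLAN."""
    ds = _load_dataset(source)
    for beam in getattr(ds, "BeamSequence", []):
        for cp in getattr(beam, "ControlPointSequence", []):
            iso = getattr(cp, "IsocenterPosition", None)
            if iso is not None:
                return np.asarray(iso, dtype=float) / 10.0
    raise ValueError("no IsocenterPosition found in RT-PLAN")
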