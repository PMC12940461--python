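"""On-disk formats: NIfTI volumes, DICOM import, JSON records, manifests.

NIfTI-1 is the canonical volume format.  Internally all coordinates are LPS
with slices ordered inferior→superior; NIfTI affines are RAS, so the x and y
axes are sign-flipped on write and read.  Only axis-aligned (diagonal-
affine) images are supported; a superior→inferior slice order is flipped on
load with the origin adjusted.

DICOM CT series and RT-STRUCT files are import-only: contours are
rasterized to voxel masks on the CT grid.

Trajectories, contours and displacement fields serialize to small JSON
records keyed by z in mm (schema version 1).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import (
    CordTrajectory,
    DisplacementField,
    ImageVolume,
    Point3,
    PolarContour,
    StructureMask,
)

JSON_SCHEMA_VERSION = 1
MANIFEST_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def _lps_affine(vol: ImageVolume) -> np.ndarray:
    dx, dy, dz = vol.spacing
    aff = np.diag([-dx, -dy, dz, 1.0])
    aff[:3, 3] = [-vol.origin.x, -vol.origin.y, vol.origin.z]
    return aff


def write_volume(vol: ImageVolume, path) -> None:
    # nibabel data axes are (i, j, k) = (x, y, z); ours are (z, y, x)
    data = np.transpose(vol.voxels, (2, 1, 0)).astype(np.float32)
    nib.save(nib.Nifti1Image(data, _lps_affine(vol)), str(path))


def write_mask(mask: StructureMask, vol: ImageVolume, path) -> None:
    data = np.transpose(mask.mask.astype(np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _lps_affine(vol)), str(path))


def read_volume(path) -> ImageVolume:
    """Load a NIfTI volume into the LPS, inferior→superior convention."""
    img = nib.load(str(path))
    aff = img.affine
    if np.any(np.abs(aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))) > 1e-6):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI supported")
    data = np.asarray(img.dataobj, dtype=np.float32)
    diag = np.diag(aff[:3, :3]).copy()
    origin_ras = aff[:3, 3].copy()
    # flip axes so that steps are (−x, −y, +z) in RAS == (+x, +y, +z) in LPS
    for axis, want_negative in ((0, True), (1, True), (2, False)):
        neg = diag[axis] < 0
        if neg != want_negative:
            data = np.flip(data, axis=axis)
            origin_ras[axis] = origin_ras[axis] + diag[axis] * (
                data.shape[axis] - 1
            )
            diag[axis] = -diag[axis]
    spacing = (abs(diag[0]), abs(diag[1]), abs(diag[2]))
    origin = Point3(-origin_ras[0], -origin_ras[1], origin_ras[2])
    return ImageVolume(np.transpose(data, (2, 1, 0)), spacing, origin)


def read_mask(path, name: str) -> StructureMask:
    vol = read_volume(path)
    return StructureMask(name, vol.voxels > 0.5)


# ---------------------------------------------------------------------------
# DICOM import
# ---------------------------------------------------------------------------


def read_dicom_series(paths) -> ImageVolume:
    """Read a DICOM CT series (list of file paths) into HU, LPS, inf→sup."""
    import pydicom

    slices = [pydicom.dcmread(str(p)) for p in paths]
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    zs = [float(d.ImagePositionPatient[2]) for d in slices]
    dz_all = np.diff(zs)
    if len(dz_all) == 0:
        raise ValueError("series needs at least 2 slices")
    if np.ptp(dz_all) > 1e-3:
        raise ValueError("inconsistent series: nonuniform slice spacing")
    dz = float(dz_all[0])
    vox = np.stack(
        [
            d.pixel_array * float(getattr(d, "RescaleSlope", 1.0))
            + float(getattr(d, "RescaleIntercept", 0.0))
            for d in slices
        ]
    )
    origin = Point3(
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        zs[0],
    )
    return ImageVolume(vox, (dx, dy, dz), origin)


def rasterize_contour_slice(
    points_xy: np.ndarray, vol: ImageVolume
) -> np.ndarray:
    """Fill one planar polygon (physical x,y mm) on the in-plane grid."""
    from skimage.draw import polygon

    pts = np.asarray(points_xy, dtype=float)
    rows = (pts[:, 1] - vol.origin.y) / vol.spacing[1]
    cols = (pts[:, 0] - vol.origin.x) / vol.spacing[0]
    out = np.zeros(vol.shape[1:], dtype=bool)
    rr, cc = polygon(rows, cols, shape=out.shape)
    out[rr, cc] = True
    return out


def read_rtstruct(path, vol: ImageVolume) -> list[StructureMask]:
    """Rasterize every ROI of a DICOM RT-STRUCT onto the CT grid."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    names = {
        int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence
    }
    slice_z = vol.slice_z
    masks = []
    for roi in ds.ROIContourSequence:
        name = names.get(int(roi.ReferencedROINumber), "roi")
        m = np.zeros(vol.shape, dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            k = int(np.argmin(np.abs(slice_z - pts[0, 2])))
            m[k] |= rasterize_contour_slice(pts[:, :2], vol)
        masks.append(StructureMask(name, m))
    return masks


# ---------------------------------------------------------------------------
# JSON records
# ---------------------------------------------------------------------------


def trajectory_to_json(traj: CordTrajectory) -> dict:
    return {
        "schema": JSON_SCHEMA_VERSION,
        "kind": "cord_trajectory",
        "slices": [
            {"z": float(z), "x": float(c[0]), "y": float(c[1])}
            for z, c in zip(traj.z, traj.centers)
        ],
    }


def trajectory_from_json(d: dict) -> CordTrajectory:
    _check_schema(d, "cord_trajectory")
    sl = d["slices"]
    return CordTrajectory(
        np.array([s["z"] for s in sl]),
        np.array([[s["x"], s["y"]] for s in sl]),
    )


def field_to_json(fieldv: DisplacementField) -> dict:
    return {
        "schema": JSON_SCHEMA_VERSION,
        "kind": "displacement_field",
        "slices": [
            {"z": float(z), "d": [float(v) for v in dv]}
            for z, dv in zip(fieldv.z, fieldv.d)
        ],
    }


def field_from_json(d: dict) -> DisplacementField:
    _check_schema(d, "displacement_field")
    sl = d["slices"]
    return DisplacementField(
        np.array([s["z"] for s in sl]), np.array([s["d"] for s in sl])
    )


def contour_to_json(c: PolarContour) -> dict:
    return {
        "schema": JSON_SCHEMA_VERSION,
        "kind": "polar_contour",
        "angles_deg": c.angles.tolist(),
        "offsets_mm": c.offsets.tolist(),
    }


def contour_from_json(d: dict) -> PolarContour:
    _check_schema(d, "polar_contour")
    return PolarContour(np.array(d["angles_deg"]), np.array(d["offsets_mm"]))


def _check_schema(d: dict, kind: str) -> None:
    if d.get("schema") != JSON_SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {d.get('schema')!r}")
    if d.get("kind") != kind:
        raise ValueError(f"expected record kind {kind!r}, got {d.get('kind')!r}")


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------


def write_manifest(entries: list[dict], params_hash: str, path) -> None:
    ids = [e["id"] for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in manifest")
    payload = {
        "schema": MANIFEST_SCHEMA_VERSION,
        "params_hash": params_hash,
        "patients": entries,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_manifest(path) -> dict:
    d = json.loads(Path(path).read_text())
    if d.get("schema") != MANIFEST_SCHEMA_VERSION:
        raise ValueError(
            f"manifest schema {d.get('schema')!r} not supported "
            f"(expected {MANIFEST_SCHEMA_VERSION})"
        )
    base = Path(path).parent
    for e in d["patients"]:
        for key in ("dct", "sct"):
            if key in e and not (base / e[key]).exists():
                raise FileNotFoundError(f"manifest references missing {e[key]}")
    return d
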