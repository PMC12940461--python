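"""Anatomical coordinate extraction and geometric correction operators.

All physical coordinates are in millimetres, LPS orientation (+x patient
left, +y posterior, +z superior).  Voxel arrays are indexed ``[k, row, col]``
with ``k`` the axial slice running inferior→superior, ``row`` along +y and
``col`` along +x.

Two sequential corrections turn a diagnostic CT (curved tabletop, no
immobilization) into a simulation-equivalent geometry:

1. a per-slice rigid in-plane translation (plus optional z-resampling) that
   moves the spinal cord onto its simulation-CT trajectory, and
2. a radial remapping of the posterior half-plane of each slice so the
   body's couch-contact surface lands on a target (flat-couch) contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

AIR_HU = -1000.0
#: physical-plausibility bound on any single per-slice displacement (mm)
MAX_DISPLACEMENT_MM = 50.0


@dataclass(frozen=True)
class Point3:
    """A point in anatomical space (mm, LPS)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("Point3 coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class ImageVolume:
    """Axial HU grid with physical spacing and origin.

    ``voxels[k, r, c]`` sits at physical position
    ``origin + (c*dx, r*dy, k*dz)``.
    """

    voxels: np.ndarray  # (nz, ny, nx) float
    spacing: tuple[float, float, float]  # (dx, dy, dz) mm
    origin: Point3

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 3:
            raise ValueError("volume must be 3-D with at least 3 slices")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def slice_z(self) -> np.ndarray:
        """Physical z of every axial slice (mm, inferior→superior)."""
        nz = self.voxels.shape[0]
        return self.origin.z + self.spacing[2] * np.arange(nz)

    def x_coords(self) -> np.ndarray:
        return self.origin.x + self.spacing[0] * np.arange(self.voxels.shape[2])

    def y_coords(self) -> np.ndarray:
        return self.origin.y + self.spacing[1] * np.arange(self.voxels.shape[1])

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.voxels.copy(), self.spacing, self.origin)


@dataclass
class StructureMask:
    """Named binary mask congruent with an :class:`ImageVolume` grid."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    def check_grid(self, vol: ImageVolume) -> None:
        if self.mask.shape != vol.shape:
            raise ValueError(
                f"mask '{self.name}' shape {self.mask.shape} does not match "
                f"volume grid {vol.shape}"
            )

    def copy(self) -> "StructureMask":
        return StructureMask(self.name, self.mask.copy())


@dataclass(frozen=True)
class HeartAnchor:
    """3-D centroid of the heart contour, the stable anatomical reference."""

    center: Point3


@dataclass
class CordTrajectory:
    """Per-slice 2-D centroids of the spinal cord.

    ``z`` is strictly increasing; slices where the cord mask is empty are
    simply absent.
    """

    z: np.ndarray  # (n,) mm
    centers: np.ndarray  # (n, 2) mm -> (x, y)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        if self.z.ndim != 1 or self.centers.shape != (self.z.size, 2):
            raise ValueError("trajectory shape mismatch")
        if self.z.size and np.any(np.diff(self.z) <= 0):
            raise ValueError("trajectory z must be strictly increasing")

    def __len__(self) -> int:
        return self.z.size

    def interp_at(self, z: np.ndarray) -> np.ndarray:
        """Linearly interpolated (x, y) centre at arbitrary z (clamped)."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        x = np.interp(z, self.z, self.centers[:, 0])
        y = np.interp(z, self.z, self.centers[:, 1])
        return np.stack([x, y], axis=-1)


@dataclass
class SpineVectorSet:
    """Heart-anchored per-slice spine vectors.

    ``V[k]`` points from the heart centre to the cord centre on the
    diagnostic CT at slice ``z[k]``; ``Vp`` is the same on the simulation CT
    and ``dV = Vp - V`` is the displacement the spine network learns.
    """

    z: np.ndarray  # (n,) mm
    V: np.ndarray  # (n, 3) mm
    Vp: np.ndarray | None = None
    dV: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if (self.Vp is None) != (self.dV is None):
            raise ValueError("Vp and dV must be present together")
        if self.Vp is not None:
            self.Vp = np.asarray(self.Vp, dtype=float)
            self.dV = np.asarray(self.dV, dtype=float)
            if not np.allclose(self.dV, self.Vp - self.V):
                raise ValueError("dV must equal Vp - V exactly")


@dataclass
class PolarContour:
    """Body-surface offsets from the spine centre at sampled angles.

    ``angles`` are degrees, uniform over [0, 180] (the posterior half-plane
    under the convention θ=0 → +x, θ=90 → +y posterior).  ``offsets[j]`` is
    the (x, y) offset in mm from the spine centre to the outermost body
    boundary along the ray at ``angles[j]``.
    """

    angles: np.ndarray  # (J,) degrees
    offsets: np.ndarray  # (J, 2) mm

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.angles.size < 19:
            raise ValueError("at least 19 angles required")
        if self.offsets.shape != (self.angles.size, 2):
            raise ValueError("offsets shape mismatch")
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("offsets must be finite")

    @property
    def radii(self) -> np.ndarray:
        return np.hypot(self.offsets[:, 0], self.offsets[:, 1])

    def radius_at(self, theta_deg: np.ndarray) -> np.ndarray:
        """Boundary radius at arbitrary angles, linear interpolation."""
        return np.interp(np.asarray(theta_deg, dtype=float), self.angles, self.radii)


@dataclass
class DisplacementField:
    """Per-slice 3-vector displacement realizing the spine correction.

    ``d[k]`` (mm) is added to the diagnostic-CT cord position at ``z[k]``.
    Outside the cord-bearing range the field is clamped to the nearest
    defined slice value.
    """

    z: np.ndarray  # (n,) mm
    d: np.ndarray  # (n, 3) mm

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (self.z.size, 3):
            raise ValueError("field shape mismatch")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("field must be finite")

    def at(self, z: np.ndarray) -> np.ndarray:
        """Field sampled at arbitrary z (linear interp, clamped ends)."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        out = np.empty((z.size, 3))
        for a in range(3):
            out[:, a] = np.interp(z, self.z, self.d[:, a])
        return out


# ---------------------------------------------------------------------------
# coordinate extraction
# ---------------------------------------------------------------------------


def centroid_of_mask(mask: StructureMask, geom: ImageVolume) -> Point3:
    """Unweighted mean of voxel-centre physical coordinates of set voxels."""
    mask.check_grid(geom)
    idx = np.argwhere(mask.mask)
    if idx.size == 0:
        raise ValueError(f"empty structure '{mask.name}'")
    dx, dy, dz = geom.spacing
    k, r, c = idx.mean(axis=0)
    return Point3(
        geom.origin.x + c * dx,
        geom.origin.y + r * dy,
        geom.origin.z + k * dz,
    )


def extract_cord_trajectory(cord: StructureMask, geom: ImageVolume) -> CordTrajectory:
    """Per-slice 2-D centroid of the cord mask; empty slices omitted."""
    cord.check_grid(geom)
    dx, dy, _ = geom.spacing
    zs, centers = [], []
    slice_z = geom.slice_z
    for k in range(geom.shape[0]):
        sl = cord.mask[k]
        if not sl.any():
            continue
        r, c = np.argwhere(sl).mean(axis=0)
        zs.append(slice_z[k])
        centers.append((geom.origin.x + c * dx, geom.origin.y + r * dy))
    if not zs:
        raise ValueError(f"cord mask '{cord.name}' empty on all slices")
    return CordTrajectory(np.array(zs), np.array(centers))


def build_spine_vectors(
    heart: HeartAnchor,
    traj_d: CordTrajectory,
    traj_s: CordTrajectory | None = None,
) -> SpineVectorSet:
    """Heart→cord vectors V (and V', ΔV when the sCT trajectory is given).

    When both trajectories are present they are matched on the sCT z grid
    restricted to the overlapping z range, with the dCT centroids linearly
    interpolated onto it.
    """
    h = heart.center.as_array()
    if traj_s is None:
        V = np.column_stack([traj_d.centers, traj_d.z]) - h
        return SpineVectorSet(z=traj_d.z.copy(), V=V)
    lo = max(traj_d.z.min(), traj_s.z.min())
    hi = min(traj_d.z.max(), traj_s.z.max())
    keep = (traj_s.z >= lo) & (traj_s.z <= hi)
    if not keep.any():
        raise ValueError("no overlapping z range between trajectories")
    z = traj_s.z[keep]
    cd = traj_d.interp_at(z)
    cs = traj_s.centers[keep]
    V = np.column_stack([cd, z]) - h
    Vp = np.column_stack([cs, z]) - h
    return SpineVectorSet(z=z, V=V, Vp=Vp, dV=Vp - V)


def sample_polar_contour(
    body_slice: np.ndarray,
    center: tuple[float, float],
    geom: ImageVolume,
    n_angles: int = 181,
) -> PolarContour:
    """Cast rays over θ∈[0°,180°] and record the outermost body crossing.

    ``body_slice`` is the 2-D body mask of one axial slice; ``center`` the
    spine centre (x, y) in mm.  The outermost crossing is used when a ray
    exits and re-enters the body, so the offset always reaches the external
    (dose-relevant) surface.
    """
    if n_angles < 19:
        raise ValueError("n_angles must be at least 19")
    body_slice = np.asarray(body_slice).astype(bool)
    dx, dy, _ = geom.spacing
    cx, cy = center
    ci = (cx - geom.origin.x) / dx
    ri = (cy - geom.origin.y) / dy
    ny, nx = body_slice.shape
    ri_n, ci_n = int(round(ri)), int(round(ci))
    if not (0 <= ri_n < ny and 0 <= ci_n < nx) or not body_slice[ri_n, ci_n]:
        raise ValueError("center outside body")

    angles = np.linspace(0.0, 180.0, n_angles)
    theta = np.deg2rad(angles)
    step = 0.25 * min(dx, dy)
    # max radius: farthest grid corner
    xs = geom.x_coords()
    ys = geom.y_coords()
    rmax = float(
        np.hypot(
            max(abs(xs[0] - cx), abs(xs[-1] - cx)),
            max(abs(ys[0] - cy), abs(ys[-1] - cy)),
        )
    )
    rr = np.arange(0.0, rmax + step, step)
    # sample positions for all rays at once: (J, n_r)
    px = cx + np.outer(np.cos(theta), rr)
    py = cy + np.outer(np.sin(theta), rr)
    col = np.rint((px - geom.origin.x) / dx).astype(int)
    row = np.rint((py - geom.origin.y) / dy).astype(int)
    ingrid = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
    inside = np.zeros_like(ingrid)
    inside[ingrid] = body_slice[row[ingrid], col[ingrid]]

    offsets = np.empty((n_angles, 2))
    for j in range(n_angles):
        ins = inside[j]
        if not ins[0]:
            raise ValueError("center outside body")
        last = np.max(np.nonzero(ins)[0])
        if last + 1 >= rr.size or not ingrid[j, last + 1]:
            raise ValueError("open contour: body reaches grid edge along ray")
        r_b = 0.5 * (rr[last] + rr[last + 1])
        offsets[j] = (r_b * np.cos(theta[j]), r_b * np.sin(theta[j]))
    return PolarContour(angles=angles, offsets=offsets)


# ---------------------------------------------------------------------------
# correction operators
# ---------------------------------------------------------------------------


def _warp_masks(masks: Sequence[StructureMask], fn) -> list[StructureMask]:
    return [StructureMask(m.name, fn(m.mask)) for m in masks]


def apply_spine_correction(
    vol: ImageVolume,
    masks: Sequence[StructureMask],
    disp: DisplacementField,
    max_displacement: float = MAX_DISPLACEMENT_MM,
) -> tuple[ImageVolume, list[StructureMask]]:
    """Translate each axial slice by its per-slice displacement.

    The z component is applied first as a 1-D resampling of slice positions,
    then each slice is shifted in-plane by (dx, dy).  HU are interpolated
    linearly (exposed voxels filled with air, −1000 HU); masks with nearest
    neighbour.
    """
    if np.max(np.abs(disp.d)) > max_displacement:
        raise ValueError(
            f"displacement exceeds plausibility bound {max_displacement} mm"
        )
    for m in masks:
        m.check_grid(vol)
    dvec = disp.at(vol.slice_z)  # (nz, 3)
    dxs, dys, dzs = dvec[:, 0], dvec[:, 1], dvec[:, 2]
    dx, dy, dz = vol.spacing
    nz = vol.shape[0]

    def warp(arr: np.ndarray, order: int, cval: float) -> np.ndarray:
        arr = arr.astype(np.float32)
        out = np.empty_like(arr)
        # z resample: output slice k reads input at k - dz_k/dz
        src_k = np.arange(nz) - dzs / dz
        for k in range(nz):
            s = src_k[k]
            if order == 0:
                # tie at exact .5 resolved toward the lower index
                si = int(np.floor(s + 0.5 - 1e-9))
                sl = arr[si] if 0 <= si < nz else np.full(arr.shape[1:], cval, arr.dtype)
            else:
                lo = int(np.floor(s))
                w = s - lo
                a = arr[lo] if 0 <= lo < nz else np.full(arr.shape[1:], cval, arr.dtype)
                b = (
                    arr[lo + 1]
                    if 0 <= lo + 1 < nz
                    else np.full(arr.shape[1:], cval, arr.dtype)
                )
                sl = (1 - w) * a + w * b
            out[k] = ndimage.shift(
                sl, (dys[k] / dy, dxs[k] / dx), order=order, cval=cval, mode="constant"
            )
        return out

    out_vol = ImageVolume(warp(vol.voxels, 1, AIR_HU), vol.spacing, vol.origin)
    out_masks = _warp_masks(masks, lambda m: warp(m, 0, 0.0) > 0.5)
    return out_vol, out_masks


def apply_body_correction(
    vol: ImageVolume,
    masks: Sequence[StructureMask],
    corrected_cord: CordTrajectory,
    target_contours: dict[float, PolarContour],
    body_name: str = "body",
    n_angles: int = 181,
) -> tuple[ImageVolume, list[StructureMask]]:
    """Radially remap the posterior half-plane onto target body contours.

    For every slice with a target contour, tissue posterior of the spine
    centre is stretched piecewise-linearly along each ray from the spine
    centre so the current body boundary lands on the target boundary.  The
    anterior half-plane is left untouched; voxels outside the new boundary
    become air.
    """
    for m in masks:
        m.check_grid(vol)
    body = next((m for m in masks if m.name == body_name), None)
    if body is None:
        raise ValueError(f"no mask named '{body_name}'")
    for z, tc in target_contours.items():
        r = tc.radii
        if np.any(~np.isfinite(r)) or np.any(r <= 0):
            raise ValueError(f"target contour at z={z} has non-positive offsets")

    out_vol = vol.copy()
    out_masks = [m.copy() for m in masks]
    slice_z = vol.slice_z
    xs = vol.x_coords()
    ys = vol.y_coords()
    X, Y = np.meshgrid(xs, ys)  # (ny, nx)
    dx, dy, _ = vol.spacing
    zmap = {round(float(z), 4): tc for z, tc in target_contours.items()}

    for k in range(vol.shape[0]):
        tc = zmap.get(round(float(slice_z[k]), 4))
        if tc is None or not body.mask[k].any():
            continue
        cx, cy = corrected_cord.interp_at(slice_z[k])[0]
        src = sample_polar_contour(body.mask[k], (cx, cy), vol, n_angles=n_angles)
        # include the voxel row straddling the midline so the θ≈0°/180° rays
        # are remapped too; anterior content strictly above it is untouched
        post = Y >= cy - 0.5 * dy
        r = np.hypot(X - cx, Y - cy)
        theta = np.degrees(np.arctan2(np.maximum(Y - cy, 0.0), X - cx))
        Rt = tc.radius_at(theta)
        Rs = src.radius_at(theta)
        scale = Rs / Rt
        # stretch along the true radial direction (θ is only the Rs/Rt key),
        # so scale == 1 reproduces the input exactly
        sx = cx + (X - cx) * scale
        sy = cy + (Y - cy) * scale
        col = (sx - vol.origin.x) / dx
        row = (sy - vol.origin.y) / dy
        outside = post & (r > Rt)
        sel = post & ~outside
        coords = np.stack([row[sel], col[sel]])
        sl = out_vol.voxels[k]
        vals = ndimage.map_coordinates(
            vol.voxels[k].astype(np.float32), coords, order=1, cval=AIR_HU,
            mode="constant",
        )
        sl[sel] = vals
        sl[outside] = AIR_HU
        for mi, m in enumerate(masks):
            src_m = m.mask[k].astype(np.float32)
            mvals = ndimage.map_coordinates(
                src_m, coords, order=0, cval=0.0, mode="constant"
            )
            osl = out_masks[mi].mask[k]
            osl[sel] = mvals > 0.5
            osl[outside] = False
    return out_vol, out_masks


def bone_centroid_translation(
    moving: ImageVolume, fixed: ImageVolume, threshold_hu: float = 200.0
) -> np.ndarray:
    """Translation (mm) aligning the bone-voxel centroids of two volumes.

    A convenience for roughly frame-aligning a scan pair before correction;
    purely translational, computed from voxels above ``threshold_hu``.
    """
    out = np.empty(3)
    for i, vol in enumerate((moving, fixed)):
        mask = StructureMask("bone", vol.voxels >= threshold_hu)
        c = centroid_of_mask(mask, vol)
        out = c.as_array() - out if i else c.as_array()
    return out


def align_by_bone_centroid(
    moving: ImageVolume,
    masks: Sequence[StructureMask],
    fixed: ImageVolume,
    threshold_hu: float = 200.0,
) -> tuple[ImageVolume, list[StructureMask]]:
    """Rigidly translate ``moving`` so its bone centroid matches ``fixed``."""
    t = bone_centroid_translation(moving, fixed, threshold_hu)
    z = moving.slice_z
    field = DisplacementField(z, np.tile(t, (z.size, 1)))
    return apply_spine_correction(moving, masks, field)


def compose_corrections(
    vol: ImageVolume,
    masks: Sequence[StructureMask],
    spine_field: DisplacementField,
    corrected_cord: CordTrajectory,
    target_contours: dict[float, PolarContour],
    body_name: str = "body",
    n_angles: int = 181,
) -> tuple[ImageVolume, list[StructureMask]]:
    """Spine correction first, body-bottom correction second."""
    v1, m1 = apply_spine_correction(vol, masks, spine_field)
    return apply_body_correction(
        v1, m1, corrected_cord, target_contours, body_name=body_name,
        n_angles=n_angles,
    )
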