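"""Seeded paired dCT/sCT phantom generator.

The generator rasterizes analytic solids (elliptical body, cylindrical cord
/ canal / vertebra, ellipsoidal heart and lungs, cylindrical PTV) on a
desk-scale grid and produces a *paired* patient:

* the simulation CT (sCT) has a flat posterior body surface (flat treatment
  couch) and a canonical spine position;
* the diagnostic CT (dCT) differs by (a) a smooth systematic plus
  patient-specific displacement of the cord/vertebra complex along the
  cranio-caudal axis, and (b) a Gaussian-in-x posterior couch sag, emulating
  the curved diagnostic tabletop.

Ground truth (the exact per-slice displacement field and paired polar body
contours) is stored alongside, so correction accuracy is measurable exactly.

The default systematic offset is calibrated so the per-patient median cord
offset falls in the 4–11 mm range typical of unimmobilized diagnostic
positioning.  Not emulated: HU texture, metal artifacts, contrast, motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from . import metrics as _metrics
from .geometry import (
    CordTrajectory,
    DisplacementField,
    HeartAnchor,
    ImageVolume,
    Point3,
    PolarContour,
    StructureMask,
    centroid_of_mask,
    extract_cord_trajectory,
    sample_polar_contour,
)

HU_SOFT = 40.0
HU_BONE = 300.0  # trabecular vertebral body, not cortical bone
HU_CANAL = 80.0
HU_LUNG = -750.0
HU_AIR = -1000.0


@dataclass
class PhantomParams:
    """Study conditions for the synthetic paired-CT cohort."""

    shape: tuple[int, int, int] = (60, 96, 96)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)  # (dx, dy, dz) mm
    body_semiaxes: tuple[float, float] = (75.0, 60.0)  # (x, y) mm
    body_center_y: float = -10.0
    flat_cut_y: float = 40.0  # flat couch surface (sCT), mm
    sag_depth: float = 12.0  # A, mm
    sag_width: float = 60.0  # w, mm
    # per-axis polynomial Δ_sys(z) = c0 + c1·z + c2·z², z centred (mm)
    sys_coeffs: dict = field(
        default_factory=lambda: {
            "x": (2.0, 0.015, 0.0),
            "y": (6.0, 0.03, 2e-4),
            "z": (0.0, 0.0, 0.0),
        }
    )
    sigma_pat: float = 1.0  # patient-specific smooth residual sd, mm
    contour_noise_sd: float = 0.0  # boundary ripple sd, mm
    rx_dose: float = 30.0  # prescription, Gy (30 Gy / 10 fx palliative)
    cord_radius: float = 4.0
    canal_radius: float = 8.0
    vertebra_radius: float = 14.0
    cord_center: tuple[float, float] = (0.0, 20.0)  # sCT (x, y) mm
    heart_center: tuple[float, float, float] = (10.0, -25.0, 10.0)
    heart_semiaxes: tuple[float, float, float] = (30.0, 25.0, 35.0)
    lung_semiaxes: tuple[float, float, float] = (26.0, 34.0, 70.0)
    ptv_radius: float = 18.0
    ptv_z_halfspan: float = 30.0
    size_variation: float = 0.15  # ±15% body-size scatter across a cohort
    n_angles: int = 61  # polar-contour resolution (3° steps at 2 mm voxels)

    def validate(self) -> None:
        if self.sag_depth < 0 or self.sigma_pat < 0 or self.rx_dose <= 0:
            raise ValueError("invalid phantom parameters")
        nx_mm = self.shape[2] * self.spacing[0] / 2
        ny_mm = self.shape[1] * self.spacing[1] / 2
        if (
            self.body_semiaxes[0] >= nx_mm
            or self.body_center_y + self.body_semiaxes[1] + self.sag_depth >= ny_mm
        ):
            raise ValueError("structures exceed grid extent")


@dataclass
class PatientPair:
    """A paired diagnostic / simulation phantom with stored ground truth."""

    dct: ImageVolume
    dct_masks: list[StructureMask]
    sct: ImageVolume
    sct_masks: list[StructureMask]
    truth_field: DisplacementField  # add to dCT cord position → sCT position
    truth_contours: list[tuple[float, PolarContour, PolarContour]]
    # (z, dCT contour about dCT cord centre, sCT contour about sCT cord centre)
    sct_cord_centers: np.ndarray  # analytic (x, y) cord centres per slice
    seed: int

    def mask(self, which: str, name: str) -> StructureMask:
        masks = self.dct_masks if which == "dct" else self.sct_masks
        for m in masks:
            if m.name == name:
                return m
        raise KeyError(name)


def _grid(params: PhantomParams):
    nz, ny, nx = params.shape
    dx, dy, dz = params.spacing
    ox = -dx * (nx - 1) / 2
    oy = -dy * (ny - 1) / 2
    oz = -dz * (nz - 1) / 2
    x = ox + dx * np.arange(nx)
    y = oy + dy * np.arange(ny)
    z = oz + dz * np.arange(nz)
    return x, y, z, Point3(ox, oy, oz)


def systematic_offset(params: PhantomParams, z: np.ndarray) -> np.ndarray:
    """Δ_sys(z): the protocol-dependent cord offset, per axis (n, 3) mm."""
    z = np.asarray(z, dtype=float)
    out = np.empty((z.size, 3))
    for a, axis in enumerate(("x", "y", "z")):
        c0, c1, c2 = params.sys_coeffs[axis]
        out[:, a] = c0 + c1 * z + c2 * z**2
    return out


def _smooth_residual(
    z: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth per-patient field, sd ≈ sigma, via a coarse spline.

    Each axis is detrended (its own linear fit removed) so the patient-
    specific part carries no systematic component: the constant and linear
    trends belong to Δ_sys and stay identifiable from cohort averages.
    """
    out = np.zeros((z.size, 3))
    if sigma <= 0:
        return out
    knots = np.linspace(z.min(), z.max(), 5)
    for a in range(2):  # in-plane only; z stays slice-matched
        vals = rng.normal(0.0, sigma, size=knots.size)
        f = CubicSpline(knots, vals)(z)
        f -= np.polyval(np.polyfit(z, f, 1), z)
        out[:, a] = f
    return out


def make_patient(params: PhantomParams, seed: int) -> PatientPair:
    """Build one paired dCT/sCT phantom with exact ground truth."""
    params.validate()
    rng = np.random.default_rng(seed)
    x, y, z, origin = _grid(params)
    X = x[None, None, :]
    Y = y[None, :, None]
    Z = z[:, None, None]

    # per-patient body size scatter
    s = 1.0 + params.size_variation * float(rng.uniform(-1.0, 1.0))
    ax, ay = params.body_semiaxes[0] * s, params.body_semiaxes[1] * s
    by = params.body_center_y * s
    flat = params.flat_cut_y * s
    ccx, ccy = params.cord_center[0] * s, params.cord_center[1] * s

    delta = systematic_offset(params, z) + _smooth_residual(
        z, params.sigma_pat, rng
    )  # dCT cord = sCT cord + delta
    # truth field maps dCT → sCT
    truth = DisplacementField(z=z.copy(), d=-delta)

    ripple = np.zeros(z.size)
    if params.contour_noise_sd > 0:
        knots = np.linspace(z.min(), z.max(), 5)
        ripple = CubicSpline(knots, rng.normal(0, params.contour_noise_sd, 5))(z)

    def build(kind: str):
        if kind == "sct":
            cx = np.full(z.size, ccx)
            cy = np.full(z.size, ccy)
            cut = np.full((z.size, x.size), flat)
        else:
            cx = ccx + delta[:, 0]
            cy = ccy + delta[:, 1]
            sag = params.sag_depth * np.exp(-(x**2) / (2 * params.sag_width**2))
            cut = flat + sag[None, :] + ripple[:, None]
        ellipse = (X / ax) ** 2 + ((Y - by) / ay) ** 2 <= 1.0
        body = ellipse & (Y <= cut[:, None, :])
        CX = cx[:, None, None]
        CY = cy[:, None, None]
        r2 = (X - CX) ** 2 + (Y - CY) ** 2
        cord = (r2 <= params.cord_radius**2) & body
        canal = (r2 <= params.canal_radius**2) & body
        vert = (r2 <= params.vertebra_radius**2) & body
        hx, hy, hz = params.heart_center
        hax, hay, haz = params.heart_semiaxes
        heart = (
            ((X - hx * s) / (hax * s)) ** 2
            + ((Y - hy * s) / (hay * s)) ** 2
            + ((Z - hz) / haz) ** 2
        ) <= 1.0
        heart &= body
        lax, lay, laz = params.lung_semiaxes
        lungs = np.zeros_like(body)
        for lx in (-45.0 * s, 45.0 * s):
            lungs |= (
                ((X - lx) / (lax * s)) ** 2
                + ((Y - (-15.0 * s)) / (lay * s)) ** 2
                + ((Z - 10.0) / laz) ** 2
            ) <= 1.0
        lungs &= body & ~vert & ~heart
        ptv = (r2 <= params.ptv_radius**2) & (
            np.abs(Z) <= params.ptv_z_halfspan
        ) & body

        hu = np.full(params.shape, HU_AIR, dtype=np.float32)
        hu[body] = HU_SOFT
        hu[lungs] = HU_LUNG
        hu[vert] = HU_BONE
        hu[canal] = HU_CANAL
        hu[cord] = HU_SOFT
        vol = ImageVolume(hu, params.spacing, origin)
        masks = [
            StructureMask("body", body),
            StructureMask("heart", heart),
            StructureMask("cord", cord),
            StructureMask("canal", canal),
            StructureMask("vertebra", vert),
            StructureMask("ptv", ptv),
        ]
        return vol, masks

    dct, dct_masks = build("dct")
    sct, sct_masks = build("sct")

    # paired polar contours about the respective cord centres
    contours = []
    dct_body = dct_masks[0]
    sct_body = sct_masks[0]
    for k in range(z.size):
        cd = sample_polar_contour(
            dct_body.mask[k], (ccx + delta[k, 0], ccy + delta[k, 1]), dct,
            n_angles=params.n_angles,
        )
        cs = sample_polar_contour(
            sct_body.mask[k], (ccx, ccy), sct, n_angles=params.n_angles
        )
        contours.append((float(z[k]), cd, cs))

    return PatientPair(
        dct=dct,
        dct_masks=dct_masks,
        sct=sct,
        sct_masks=sct_masks,
        truth_field=truth,
        truth_contours=contours,
        sct_cord_centers=np.tile([ccx, ccy], (z.size, 1)),
        seed=seed,
    )


def derive_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def make_cohort(
    n: int, params: PhantomParams, master_seed: int
) -> list[PatientPair]:
    """n independent patients with deterministically derived per-patient seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [make_patient(params, derive_seed(master_seed, i)) for i in range(n)]


def heart_anchor_of(pair: PatientPair) -> HeartAnchor:
    """Heart anchor from the dCT heart contour (the anchor the networks use)."""
    return HeartAnchor(centroid_of_mask(pair.mask("dct", "heart"), pair.dct))


def truth_errors(
    pair: PatientPair,
    corrected: ImageVolume,
    corrected_masks: list[StructureMask],
) -> dict:
    """Geometric error bundle of a corrected volume against the sCT truth.

    Returns trajectory RMS (mm), posterior-contour MAE (mm), and spinal-canal
    Dice / HD95 relative to the paired simulation CT.
    """
    if corrected.shape != pair.sct.shape:
        raise ValueError("corrected volume grid does not match the sCT grid")

    def get(masks, name):
        for m in masks:
            if m.name == name:
                return m
        raise KeyError(name)

    traj_c = extract_cord_trajectory(get(corrected_masks, "cord"), corrected)
    traj_s = extract_cord_trajectory(pair.mask("sct", "cord"), pair.sct)
    lo = max(traj_c.z.min(), traj_s.z.min())
    hi = min(traj_c.z.max(), traj_s.z.max())
    zz = traj_s.z[(traj_s.z >= lo) & (traj_s.z <= hi)]
    diff = traj_c.interp_at(zz) - traj_s.interp_at(zz)
    traj_rms = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))

    body_c = get(corrected_masks, "body")
    slice_z = corrected.slice_z
    errs = []
    for j, (zk, _cd, cs) in enumerate(pair.truth_contours):
        k = int(np.argmin(np.abs(slice_z - zk)))
        if not body_c.mask[k].any():
            continue
        center = pair.sct_cord_centers[j]
        try:
            cc = sample_polar_contour(
                body_c.mask[k], tuple(center), corrected, n_angles=cs.angles.size
            )
        except ValueError:
            continue
        errs.append(np.mean(np.abs(cc.radii - cs.radii)))
    contour_mae = float(np.mean(errs)) if errs else float("nan")

    canal_c = get(corrected_masks, "canal")
    canal_s = pair.mask("sct", "canal")
    return {
        "trajectory_rms_mm": traj_rms,
        "contour_mae_mm": contour_mae,
        "canal_dice": _metrics.dice(canal_c, canal_s),
        "canal_hd95_mm": _metrics.hd95(canal_c, canal_s, corrected.spacing),
    }
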