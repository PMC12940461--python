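"""Minimal deterministic dose engine for geometric-sensitivity studies.

This is a parallel-beam, primary-only exponential attenuation model — a toy
engine by design.  It exists so DVH-level comparisons between planning
geometries can be exercised end-to-end at desk scale; it makes no claim to
clinical dose accuracy (no scatter, no buildup, no beam model).

Attenuation uses μ = μ_w · (HU + 1000)/1000 clamped at ≥ 0, with
μ_w = 0.02 /mm for water.  ``plan_on`` normalizes the PTV mean dose to the
prescription and returns the normalization factor; ``recalc_on`` applies the
*same* beams and factor to a different geometry without renormalization
(monitor-unit transfer), isolating the geometric dose effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import ImageVolume, StructureMask

MU_WATER_PER_MM = 0.02


@dataclass
class BeamConfig:
    """Axial parallel beams: gantry 0° enters anteriorly and travels +y (LPS);
    90° enters from the patient's left (+x side) and travels −x."""

    gantry_deg: tuple[float, ...] = (0.0, 180.0)  # opposed AP/PA pair
    weights: tuple[float, ...] | None = None
    rx_gy: float = 30.0
    mu_water: float = MU_WATER_PER_MM  # 1/mm

    def __post_init__(self):
        if len(self.gantry_deg) < 1:
            raise ValueError("at least one beam required")
        if self.weights is None:
            self.weights = tuple(1.0 for _ in self.gantry_deg)
        if len(self.weights) != len(self.gantry_deg):
            raise ValueError("one weight per beam required")
        if any(w <= 0 for w in self.weights) or self.rx_gy <= 0:
            raise ValueError("weights and prescription must be positive")


@dataclass
class DoseGrid:
    values: np.ndarray  # Gy, congruent with the ImageVolume grid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("dose must be finite and non-negative")


def _mu(vol: ImageVolume, mu_water: float) -> np.ndarray:
    return np.maximum(mu_water * (vol.voxels.astype(np.float64) + 1000.0) / 1000.0, 0.0)


def _attenuation_along_y(mu: np.ndarray, dy: float, reverse: bool) -> np.ndarray:
    """exp(−∫μ dl) to each voxel centre for a beam travelling ±y."""
    m = mu[:, ::-1, :] if reverse else mu
    path = np.cumsum(m * dy, axis=1) - 0.5 * m * dy
    att = np.exp(-path)
    return att[:, ::-1, :] if reverse else att


def _beam_dose(mu: np.ndarray, spacing, gantry: float) -> np.ndarray:
    dx, dy, _ = spacing
    g = gantry % 360.0
    if np.isclose(g % 90.0, 0.0):
        q = int(round(g / 90.0)) % 4
        if q == 0:  # travels +y
            return _attenuation_along_y(mu, dy, reverse=False)
        if q == 2:  # travels -y
            return _attenuation_along_y(mu, dy, reverse=True)
        # 90°: source at +x, travels -x  → rotate so -x maps to +y
        # 270°: source at -x, travels +x
        k = 1 if q == 1 else 3
        mrot = np.rot90(mu, k=k, axes=(1, 2))
        att = _attenuation_along_y(mrot, dx, reverse=False)
        return np.rot90(att, k=-k, axes=(1, 2))
    # general angle: rotate the slice stack so the beam travels +row
    mrot = ndimage.rotate(
        mu, angle=-g, axes=(2, 1), reshape=False, order=1, cval=0.0,
        mode="constant",
    )
    att = _attenuation_along_y(mrot, dy, reverse=False)
    return ndimage.rotate(
        att, angle=g, axes=(2, 1), reshape=False, order=1, cval=0.0,
        mode="constant",
    )


def _raw_dose(vol: ImageVolume, beams: BeamConfig) -> np.ndarray:
    mu = _mu(vol, beams.mu_water)
    dose = np.zeros_like(mu)
    for g, w in zip(beams.gantry_deg, beams.weights):
        dose += w * _beam_dose(mu, vol.spacing, g)
    return np.maximum(dose, 0.0)


def plan_on(
    vol: ImageVolume, ptv: StructureMask, beams: BeamConfig
) -> tuple[DoseGrid, float]:
    """Compute dose on the planning image, normalized so PTV mean = Rx."""
    ptv.check_grid(vol)
    if not ptv.mask.any():
        raise ValueError("empty structure 'ptv'")
    raw = _raw_dose(vol, beams)
    mean_ptv = float(raw[ptv.mask].mean())
    if mean_ptv <= 0:
        raise ValueError("PTV receives no primary dose")
    factor = beams.rx_gy / mean_ptv
    return DoseGrid(raw * factor), factor


def recalc_on(
    vol2: ImageVolume,
    beams: BeamConfig,
    factor: float,
    grid_shape: tuple[int, int, int] | None = None,
) -> DoseGrid:
    """Apply the same beams and monitor-unit factor on another geometry.

    ``grid_shape`` (when given) must match the planning grid so dose grids
    stay voxel-comparable across geometries.
    """
    if grid_shape is not None and vol2.shape != tuple(grid_shape):
        raise ValueError(
            f"grid shape {vol2.shape} does not match planning grid {grid_shape}"
        )
    raw = _raw_dose(vol2, beams)
    return DoseGrid(raw * factor)
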