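"""Geometric and dosimetric evaluation: Dice, HD95, DVH endpoints, goal pass.

Conventions that treatment-planning systems do not agree on are pinned here:

* D95/D99 use the lower-interpolated order statistic — the largest dose such
  that at least 95% (99%) of the ROI volume receives ≥ it.
* V100/V107 are percentages of ROI volume receiving ≥ 100%/107% of the
  *prescription* (not of Dmax).
* DVH curves are sampled from 0 to 1.15·Rx in 0.5%-of-Rx steps; the RMS DVH
  difference is computed pointwise on that shared axis.
* Dice of two empty masks is defined as 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .dose import DoseGrid
from .geometry import StructureMask


def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|)."""
    if a.mask.shape != b.mask.shape:
        raise ValueError("masks are on different grids")
    na, nb = int(a.mask.sum()), int(b.mask.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int((a.mask & b.mask).sum())
    return 2.0 * inter / (na + nb)


def _surface_coords(mask: np.ndarray, spacing) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, border_value=0)
    surf = mask & ~eroded
    idx = np.argwhere(surf)  # (n, 3) as (k, r, c)
    dx, dy, dz = spacing
    return idx[:, [2, 1, 0]] * np.array([dx, dy, dz])


def hd95(a: StructureMask, b: StructureMask, spacing) -> float:
    """Symmetric 95th-percentile Hausdorff distance between mask surfaces (mm)."""
    if a.mask.shape != b.mask.shape:
        raise ValueError("masks are on different grids")
    if not a.mask.any() or not b.mask.any():
        raise ValueError("hd95 requires nonempty masks")
    pa = _surface_coords(a.mask, spacing)
    pb = _surface_coords(b.mask, spacing)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


@dataclass
class DVHCurve:
    """Cumulative DVH: % of ROI volume receiving ≥ each dose level."""

    dose_gy: np.ndarray
    volume_pct: np.ndarray

    def __post_init__(self):
        self.dose_gy = np.asarray(self.dose_gy, float)
        self.volume_pct = np.asarray(self.volume_pct, float)
        if self.dose_gy.shape != self.volume_pct.shape:
            raise ValueError("axis mismatch")
        if np.any(np.diff(self.volume_pct) > 1e-9):
            raise ValueError("DVH must be non-increasing")
        if self.volume_pct[0] != 100.0 or np.any(
            (self.volume_pct < 0) | (self.volume_pct > 100)
        ):
            raise ValueError("DVH values must start at 100 and lie in [0, 100]")


@dataclass(frozen=True)
class DVHMetrics:
    dmean_gy: float
    dmax_gy: float
    d95_gy: float
    d99_gy: float
    v100_pct: float
    v107_pct: float

    def as_dict(self) -> dict:
        return {
            "Dmean": self.dmean_gy,
            "Dmax": self.dmax_gy,
            "D95": self.d95_gy,
            "D99": self.d99_gy,
            "V100": self.v100_pct,
            "V107": self.v107_pct,
        }


def _roi_doses(dose: DoseGrid, roi: StructureMask) -> np.ndarray:
    if dose.values.shape != roi.mask.shape:
        raise ValueError("dose grid and ROI are on different grids")
    if not roi.mask.any():
        raise ValueError("empty ROI")
    return dose.values[roi.mask]


def compute_dvh(
    dose: DoseGrid, roi: StructureMask, rx_gy: float, step_fraction: float = 0.005
) -> DVHCurve:
    """Cumulative DVH on a uniform axis from 0 to 1.15·Rx."""
    d = _roi_doses(dose, roi)
    axis = np.arange(0.0, 1.15 * rx_gy + 1e-9, step_fraction * rx_gy)
    vol = np.array([100.0 * np.mean(d >= lev) for lev in axis])
    return DVHCurve(axis, vol)


def _dxx(doses: np.ndarray, fraction: float) -> float:
    """Largest dose received by at least ``fraction`` of the volume."""
    a = np.sort(doses)
    n = a.size
    k = int(np.floor((1.0 - fraction) * n + 1e-12))
    k = min(k, n - 1)
    return float(a[k])


def dvh_metrics(dose: DoseGrid, roi: StructureMask, rx_gy: float) -> DVHMetrics:
    d = _roi_doses(dose, roi)
    return DVHMetrics(
        dmean_gy=float(d.mean()),
        dmax_gy=float(d.max()),
        d95_gy=_dxx(d, 0.95),
        d99_gy=_dxx(d, 0.99),
        v100_pct=float(100.0 * np.mean(d >= 1.00 * rx_gy)),
        v107_pct=float(100.0 * np.mean(d >= 1.07 * rx_gy)),
    )


def rms_dvh_error(a: DVHCurve, b: DVHCurve) -> float:
    """Root-mean-square pointwise volume-% difference over the shared axis."""
    if a.dose_gy.shape != b.dose_gy.shape or not np.allclose(a.dose_gy, b.dose_gy):
        raise ValueError("DVH dose axes do not match")
    return float(np.sqrt(np.mean((a.volume_pct - b.volume_pct) ** 2)))


@dataclass
class GoalSet:
    """Institutional dose constraints with a fractional clinical tolerance."""

    goals: list[tuple[str, float, str]]  # (metric, limit, ">=" or "<=")
    tolerance: float = 0.02

    def __post_init__(self):
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        for _, _, direction in self.goals:
            if direction not in (">=", "<="):
                raise ValueError(f"bad goal direction {direction!r}")


def plan_goal_pass(m: DVHMetrics, goals: GoalSet) -> tuple[dict, bool]:
    """Per-goal pass flags (±tolerance band) and the plan-level conjunction."""
    values = m.as_dict()
    result = {}
    for name, limit, direction in goals.goals:
        if name not in values:
            raise ValueError(f"unknown metric {name!r}")
        v = values[name]
        if direction == ">=":
            ok = v >= limit * (1.0 - goals.tolerance)
        else:
            ok = v <= limit * (1.0 + goals.tolerance)
        result[name] = bool(ok)
    return result, all(result.values())
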