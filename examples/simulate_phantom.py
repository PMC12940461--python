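"""Generate one paired diagnostic/simulation phantom and inspect its gap.

The diagnostic CT differs from the simulation CT by a posterior couch sag
and a smooth spinal displacement; both are stored as exact ground truth.
"""

import numpy as np

from spinewarp import PhantomParams, make_patient
from spinewarp.geometry import extract_cord_trajectory

pair = make_patient(PhantomParams(), seed=7)

offsets = np.linalg.norm(pair.truth_field.d[:, :2], axis=1)
print(f"grid: {pair.dct.shape}, spacing {pair.dct.spacing} mm")
print(f"per-slice cord offset dCT→sCT: median {np.median(offsets):.1f} mm, "
      f"range {offsets.min():.1f}–{offsets.max():.1f} mm")

traj_d = extract_cord_trajectory(pair.mask("dct", "cord"), pair.dct)
traj_s = extract_cord_trajectory(pair.mask("sct", "cord"), pair.sct)
mid = len(traj_d) // 2
print(f"cord centre at mid-thorax: dCT ({traj_d.centers[mid][0]:+.1f}, "
      f"{traj_d.centers[mid][1]:+.1f}) mm vs sCT "
      f"({traj_s.centers[mid][0]:+.1f}, {traj_s.centers[mid][1]:+.1f}) mm")

# posterior body surface: the dCT sags into the curved tabletop
k = pair.dct.shape[0] // 2
ys = pair.dct.y_coords()
mid_cols = slice(pair.dct.shape[2] // 2 - 2, pair.dct.shape[2] // 2 + 3)
bot_d = ys[np.argwhere(pair.mask("dct", "body").mask[k][:, mid_cols])[:, 0].max()]
bot_s = ys[np.argwhere(pair.mask("sct", "body").mask[k][:, mid_cols])[:, 0].max()]
print(f"posterior surface at couch centre: dCT {bot_d:+.0f} mm vs "
      f"sCT {bot_s:+.0f} mm (sag ≈ {bot_d - bot_s:.0f} mm)")
print("-> the two learned corrections must remove exactly these two gaps.")
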