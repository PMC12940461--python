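# spinewarp

Simulation-free planning-CT adaptation for spine palliative radiotherapy.

## The problem

Palliative radiotherapy of spinal metastases is time-critical, yet planning
normally waits for a dedicated simulation CT (sCT: flat couch,
immobilization). A diagnostic CT (dCT) is usually available much earlier,
but it was acquired on a curved tabletop without immobilization, so two
systematic geometric gaps separate it from treatment conditions:

1. the spinal cord/vertebra complex sits in a different position, with a
   smooth, protocol-dependent offset along the cranio-caudal axis, and
2. the posterior body surface sags into the curved tabletop instead of
   resting on a flat couch.

Both gaps are systematic — they come from positioning protocol, not from
arbitrary anatomy — so the mapping from diagnostic to simulation geometry is
learnable. `spinewarp` learns it with two small fully connected networks and
applies it, turning a dCT into a simulation-equivalent planning volume
(AI-pCT), then quantifies the geometric and dosimetric consequences.

## The model

A point `p` is mapped by `T_θ(p) = p + Δ_sys(p) + Δ_pat(p)`, the sum of a
systematic protocol offset and a patient-specific residual, learned jointly.
The loss is the MSE between predicted and reference displacements plus a
smoothness penalty `λ·‖∇T_θ‖²` (realized as the mean squared finite
difference of predictions between z-adjacent slices), trained with Adam
(lr 10⁻³, weight decay 10⁻⁵), one patient per batch.

* **Spine network** — input: heart-contour centroid `(X,Y,Z)` and the
  per-slice heart→cord vector `V`; output: the per-slice displacement
  `ΔV = V′ − V` onto the sCT cord trajectory. Architecture 64-128-64, ReLU.
* **Body network** — input: heart centroid, the corrected spine vector
  `V+ΔV`, and the body-surface polar offsets `[x(θ), y(θ)]` from the spine
  centre for θ ∈ [0°, 180°] (posterior half-plane); output: the flat-couch
  offsets on the same angles. Same architecture and regime.

The corrections compose as `AI-pCT = T_body(T_spine(dCT))`: first each axial
slice is rigidly translated onto the corrected cord trajectory, then
posterior tissue is radially remapped so the couch-contact surface lands on
the predicted flat contour.

Evaluation follows standard planning practice: spinal-canal Dice and HD95
against the sCT, PTV DVH endpoints (Dmean, Dmax, D95, D99, V100, V107), RMS
DVH difference, plan-level goal pass within ±2% of institutional limits,
Wilcoxon signed-rank tests on paired errors, and observer agreement
(exact-match %, ≤1-step %, Gwet's AC2 with quadratic weights).

Because paired clinical CTs cannot be shipped, the package includes a
seeded phantom generator producing paired dCT/sCT volumes with exact ground
truth, and a deliberately minimal parallel-beam dose engine (primary
attenuation only — **not** a clinical dose calculation) so the dosimetric
chain can be exercised end to end.

## Worked example

```bash
python examples/train_and_correct.py
```

trains both networks on 8 synthetic patients and corrects a held-out one:

```
spine network: training MAE 0.16 mm (369 epochs)
body network:  training MAE 1.10 mm (300 epochs)
trajectory_rms_mm :   7.40 ->   0.94 mm
contour_mae_mm    :   6.25 ->   1.77 mm
canal_dice        :   0.44 ->   0.89
canal_hd95_mm     :   8.94 ->   2.00 mm
```

The held-out patient's cord trajectory error drops from 7.4 mm to under one
in-plane voxel, and the spinal-canal overlap with the simulation CT rises
from 0.44 to 0.89 Dice. `examples/dose_comparison.py` continues to dose:

```
image      Dmean     D95    V100  goals
sCT        30.00   24.42   46.9%   pass
dCT        25.63   21.42   10.4%   FAIL
AI-pCT     30.30   24.30   48.4%   pass
```

The same fixed plan under-doses the PTV by ~15% of prescription on the raw
dCT (extra sagged tissue in the posterior beam path plus a shifted target)
and fails the institutional goals; on the corrected volume the sCT dose is
restored. `examples/simulate_phantom.py` and
`examples/observer_agreement.py` demonstrate the generator and the
agreement statistics.

There is also a thin CLI:

```bash
spinewarp simulate --n 8 --seed 7 --out cohort/
spinewarp run --seed 1 --out results/
spinewarp agreement --ratings ratings.csv
```

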