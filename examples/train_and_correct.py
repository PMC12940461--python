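"""Train both correction networks on a small cohort and correct a held-out
patient, then measure the residual geometric error against ground truth."""

from spinewarp import PhantomParams, TrainConfig, make_cohort, truth_errors
from spinewarp.pipeline import correct_patient, train_models

params = PhantomParams()
pairs = make_cohort(10, params, master_seed=1)
train, held = pairs[:8], pairs[8]

spine_model, srep, body_model, brep = train_models(
    train,
    TrainConfig(epochs=600, seed=0),
    TrainConfig(epochs=300, seed=1),
)
print(f"spine network: training MAE {srep.final_mae_vector:.2f} mm "
      f"({len(srep.loss_curve)} epochs)")
print(f"body network:  training MAE {brep.final_mae_vector:.2f} mm "
      f"({len(brep.loss_curve)} epochs)")

corrected, masks = correct_patient(held, spine_model, body_model)
before = truth_errors(held, held.dct, held.dct_masks)
after = truth_errors(held, corrected, masks)
for key, unit in (
    ("trajectory_rms_mm", "mm"),
    ("contour_mae_mm", "mm"),
    ("canal_dice", ""),
    ("canal_hd95_mm", "mm"),
):
    print(f"{key:18s}: {before[key]:6.2f} -> {after[key]:6.2f} {unit}")
print("-> cord trajectory and couch-contact surface land on the simulation-"
      "CT geometry; the spinal canal overlap (Dice) rises accordingly.")
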