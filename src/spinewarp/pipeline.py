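"""End-to-end workflow: simulate → train → correct → dose → evaluate.

The pipeline mirrors the clinical evaluation design: a plan is normalized on
the simulation CT (the gold standard), then recalculated with identical
beams and monitor units on the uncorrected diagnostic CT and on the
corrected volume (AI-pCT).  Geometric (canal Dice/HD95, cord-trajectory RMS)
and dosimetric (DVH endpoint errors, RMS DVH difference, plan-level goal
pass) comparisons quantify how much of the positioning-induced error the two
learned corrections remove.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import stats as _stats
from .dose import BeamConfig, plan_on, recalc_on
from .geometry import (
    CordTrajectory,
    DisplacementField,
    ImageVolume,
    StructureMask,
    apply_body_correction,
    apply_spine_correction,
    build_spine_vectors,
    extract_cord_trajectory,
    sample_polar_contour,
)
from .metrics import (
    DVHMetrics,
    GoalSet,
    compute_dvh,
    dvh_metrics,
    plan_goal_pass,
    rms_dvh_error,
)
from .models import (
    BodyPatient,
    BodySlice,
    SpinePatient,
    TrainConfig,
    TrainedModel,
    predict_body_contour,
    predict_spine_displacement,
    train_body_model,
    train_spine_model,
)
from .phantom import (
    PatientPair,
    PhantomParams,
    heart_anchor_of,
    make_cohort,
    truth_errors,
)

# Default institutional-style goal set for the toy engine's mean-normalized
# palliative plans (Rx 30 Gy): coverage floor at 75% Rx, a V100 floor, and a
# hotspot ceiling.  Strict conformity goals (e.g. V100 ≥ 95%) are available
# through GoalSet but are rarely achievable under mean normalization.
DEFAULT_GOALS = GoalSet(
    goals=[("D95", 22.5, ">="), ("V100", 40.0, ">="), ("Dmax", 42.0, "<=")]
)


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort run."""

    n_train: int = 40
    n_test: int = 8
    phantom: PhantomParams = field(default_factory=PhantomParams)
    spine_epochs: int = 800
    body_epochs: int = 400
    smoothness_lambda: float = 0.01
    beams: BeamConfig = field(default_factory=BeamConfig)
    goals: GoalSet = field(default_factory=lambda: DEFAULT_GOALS)
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        cfg = cls()
        for key in ("n_train", "n_test", "spine_epochs", "body_epochs",
                    "smoothness_lambda", "seed"):
            if key in d:
                setattr(cfg, key, d[key])
        if "phantom" in d:
            cfg.phantom = PhantomParams(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["phantom"].items()
            })
        if "beams" in d:
            b = dict(d["beams"])
            for k in ("gantry_deg", "weights"):
                if k in b and b[k] is not None:
                    b[k] = tuple(b[k])
            cfg.beams = BeamConfig(**b)
        if "goals" in d:
            cfg.goals = GoalSet(
                goals=[tuple(g) for g in d["goals"]["goals"]],
                tolerance=d["goals"].get("tolerance", 0.02),
            )
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def extract_spine_patient(pair: PatientPair) -> SpinePatient:
    """Heart anchor plus matched dCT/sCT spine vectors for one patient."""
    heart = heart_anchor_of(pair)
    traj_d = extract_cord_trajectory(pair.mask("dct", "cord"), pair.dct)
    traj_s = extract_cord_trajectory(pair.mask("sct", "cord"), pair.sct)
    return SpinePatient(heart=heart, vectors=build_spine_vectors(heart, traj_d, traj_s))


def extract_body_patient(
    pair: PatientPair, spine_model: TrainedModel
) -> BodyPatient:
    """Body-network training rows using the AI-corrected spine vector."""
    heart = heart_anchor_of(pair)
    traj_d = extract_cord_trajectory(pair.mask("dct", "cord"), pair.dct)
    vectors = build_spine_vectors(heart, traj_d)
    disp = predict_spine_displacement(spine_model, heart, vectors)
    corrected_V = vectors.V + disp.d
    zmap = {round(z, 4): i for i, z in enumerate(vectors.z)}
    slices = []
    for z, cd, cs in pair.truth_contours:
        i = zmap.get(round(z, 4))
        if i is None:
            continue
        slices.append(
            BodySlice(z=z, corrected_vector=corrected_V[i], contour_d=cd,
                      contour_s=cs)
        )
    return BodyPatient(heart=heart, slices=slices)


def train_models(
    train_pairs: list[PatientPair],
    spine_config: TrainConfig,
    body_config: TrainConfig,
):
    """Train the spine-displacement and body-contour networks in sequence."""
    spine_cohort = [extract_spine_patient(p) for p in train_pairs]
    spine_model, spine_report = train_spine_model(spine_cohort, spine_config)
    body_cohort = [extract_body_patient(p, spine_model) for p in train_pairs]
    body_model, body_report = train_body_model(body_cohort, body_config)
    return spine_model, spine_report, body_model, body_report


# ---------------------------------------------------------------------------
# correction of one patient
# ---------------------------------------------------------------------------


def correct_patient(
    pair: PatientPair,
    spine_model: TrainedModel,
    body_model: TrainedModel,
    n_angles: int | None = None,
) -> tuple[ImageVolume, list[StructureMask]]:
    """Produce the corrected planning volume for one diagnostic CT."""
    heart = heart_anchor_of(pair)
    traj_d = extract_cord_trajectory(pair.mask("dct", "cord"), pair.dct)
    vectors = build_spine_vectors(heart, traj_d)
    disp = predict_spine_displacement(spine_model, heart, vectors)
    vol1, masks1 = apply_spine_correction(pair.dct, pair.dct_masks, disp)

    def get(masks, name):
        return next(m for m in masks if m.name == name)

    traj_c = extract_cord_trajectory(get(masks1, "cord"), vol1)
    corrected_V = vectors.V + disp.d
    vmap = {round(z, 4): i for i, z in enumerate(vectors.z)}
    if n_angles is None:
        n_angles = int(getattr(body_model, "angles", np.arange(61)).size)

    body1 = get(masks1, "body")
    targets: dict[float, "object"] = {}
    for k, z in enumerate(vol1.slice_z):
        if not body1.mask[k].any():
            continue
        center = traj_c.interp_at(z)[0]
        try:
            cd = sample_polar_contour(body1.mask[k], tuple(center), vol1,
                                      n_angles=n_angles)
        except ValueError:
            continue
        i = vmap.get(round(float(z), 4))
        vec = corrected_V[i] if i is not None else np.array(
            [center[0], center[1], z]
        ) - heart.center.as_array()
        targets[float(z)] = predict_body_contour(body_model, heart, vec, cd)

    return apply_body_correction(vol1, masks1, traj_c, targets,
                                 n_angles=n_angles)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _dose_errors(m: DVHMetrics, ref: DVHMetrics, rx: float) -> dict:
    """Endpoint errors vs the sCT reference, in % of prescription for dose
    endpoints and percentage points for volume endpoints."""
    return {
        "Dmean": 100.0 * abs(m.dmean_gy - ref.dmean_gy) / rx,
        "Dmax": 100.0 * abs(m.dmax_gy - ref.dmax_gy) / rx,
        "D95": 100.0 * abs(m.d95_gy - ref.d95_gy) / rx,
        "D99": 100.0 * abs(m.d99_gy - ref.d99_gy) / rx,
        "V100": abs(m.v100_pct - ref.v100_pct),
        "V107": abs(m.v107_pct - ref.v107_pct),
    }


def evaluate_patient(
    pair: PatientPair,
    corrected: ImageVolume,
    corrected_masks: list[StructureMask],
    beams: BeamConfig,
    goals: GoalSet,
) -> dict:
    """Geometric and dosimetric report for one test patient."""
    rx = beams.rx_gy
    ptv_s = pair.mask("sct", "ptv")
    dose_s, factor = plan_on(pair.sct, ptv_s, beams)
    dose_d = recalc_on(pair.dct, beams, factor, grid_shape=pair.sct.shape)
    dose_c = recalc_on(corrected, beams, factor, grid_shape=pair.sct.shape)

    # DVH comparisons are made on the sCT PTV (the planning structure)
    m_s = dvh_metrics(dose_s, ptv_s, rx)
    m_d = dvh_metrics(dose_d, ptv_s, rx)
    m_c = dvh_metrics(dose_c, ptv_s, rx)
    dvh_s = compute_dvh(dose_s, ptv_s, rx)
    dvh_d = compute_dvh(dose_d, ptv_s, rx)
    dvh_c = compute_dvh(dose_c, ptv_s, rx)

    geo_d = truth_errors(pair, pair.dct, pair.dct_masks)
    geo_c = truth_errors(pair, corrected, corrected_masks)

    _, pass_d = plan_goal_pass(m_d, goals)
    _, pass_c = plan_goal_pass(m_c, goals)
    _, pass_s = plan_goal_pass(m_s, goals)

    return {
        "geometry": {"dct": geo_d, "aipct": geo_c},
        "dvh_metrics": {
            "sct": m_s.as_dict(), "dct": m_d.as_dict(), "aipct": m_c.as_dict()
        },
        "dvh_errors": {
            "dct": _dose_errors(m_d, m_s, rx),
            "aipct": _dose_errors(m_c, m_s, rx),
        },
        "rms_dvh": {
            "dct": rms_dvh_error(dvh_d, dvh_s),
            "aipct": rms_dvh_error(dvh_c, dvh_s),
        },
        "goal_pass": {"sct": pass_s, "dct": pass_d, "aipct": pass_c},
    }


def summarize(per_patient: list[dict]) -> dict:
    """Cohort-level means, pass rates and paired Wilcoxon p-values."""
    out: dict = {"n": len(per_patient)}
    for img in ("dct", "aipct"):
        out[img] = {
            "trajectory_rms_mm": float(np.mean(
                [p["geometry"][img]["trajectory_rms_mm"] for p in per_patient]
            )),
            "contour_mae_mm": float(np.mean(
                [p["geometry"][img]["contour_mae_mm"] for p in per_patient]
            )),
            "canal_dice": float(np.mean(
                [p["geometry"][img]["canal_dice"] for p in per_patient]
            )),
            "canal_hd95_mm": float(np.mean(
                [p["geometry"][img]["canal_hd95_mm"] for p in per_patient]
            )),
            "rms_dvh_pct": float(np.mean(
                [p["rms_dvh"][img] for p in per_patient]
            )),
            "goal_pass_rate_pct": float(100.0 * np.mean(
                [p["goal_pass"][img] for p in per_patient]
            )),
        }
        for metric in ("Dmean", "Dmax", "D95", "D99", "V100", "V107"):
            out[img][f"{metric}_err"] = float(np.mean(
                [p["dvh_errors"][img][metric] for p in per_patient]
            ))
    out["wilcoxon_p"] = {}
    for metric in ("Dmean", "V100"):
        e_d = [p["dvh_errors"]["dct"][metric] for p in per_patient]
        e_c = [p["dvh_errors"]["aipct"][metric] for p in per_patient]
        try:
            _, pval = _stats.wilcoxon_signed_rank(np.array(e_d), np.array(e_c))
        except ValueError:
            pval = float("nan")
        out["wilcoxon_p"][metric] = pval
    return out


def run_pipeline(config: RunConfig, out_dir=None, log=print) -> dict:
    """Simulate, train, correct, and evaluate; returns the full report."""
    t0 = time.time()
    chash = config.config_hash()
    log(f"[simulate] seed={config.seed} config={chash}")
    pairs = make_cohort(
        config.n_train + config.n_test, config.phantom, config.seed
    )
    train_pairs = pairs[: config.n_train]
    test_pairs = pairs[config.n_train:]

    spine_cfg = TrainConfig(
        epochs=config.spine_epochs,
        smoothness_lambda=config.smoothness_lambda,
        seed=config.seed,
    )
    body_cfg = TrainConfig(
        epochs=config.body_epochs,
        smoothness_lambda=config.smoothness_lambda,
        seed=config.seed + 1,
    )
    log(f"[train] spine epochs<={spine_cfg.epochs} body epochs<={body_cfg.epochs}")
    spine_model, spine_rep, body_model, body_rep = train_models(
        train_pairs, spine_cfg, body_cfg
    )
    log(
        f"[train] spine MAE={spine_rep.final_mae_vector:.3f} mm "
        f"({len(spine_rep.loss_curve)} epochs), "
        f"body MAE={body_rep.final_mae_vector:.3f} mm "
        f"({len(body_rep.loss_curve)} epochs)"
    )

    per_patient = []
    for i, pair in enumerate(test_pairs):
        corrected, cmasks = correct_patient(pair, spine_model, body_model)
        rep = evaluate_patient(pair, corrected, cmasks, config.beams,
                               config.goals)
        per_patient.append(rep)
        log(
            f"[evaluate] patient {i}: canal dice "
            f"{rep['geometry']['dct']['canal_dice']:.2f}→"
            f"{rep['geometry']['aipct']['canal_dice']:.2f}"
        )

    report = {
        "config_hash": chash,
        "seed": config.seed,
        "train_mae_mm": {
            "spine": spine_rep.final_mae_vector,
            "body": body_rep.final_mae_vector,
        },
        "per_patient": per_patient,
        "summary": summarize(per_patient),
        "elapsed_s": round(time.time() - t0, 2),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        _write_csv(per_patient, out / "report.csv")
        spine_model.save(out / "spine_model.json")
        body_model.save(out / "body_model.json")
    return report


def _write_csv(per_patient: list[dict], path) -> None:
    import pandas as pd

    rows = []
    for i, p in enumerate(per_patient):
        for img in ("dct", "aipct"):
            row = {"patient": i, "image": img}
            row.update({f"geo_{k}": v for k, v in p["geometry"][img].items()})
            row.update({f"err_{k}": v for k, v in p["dvh_errors"][img].items()})
            row["rms_dvh_pct"] = p["rms_dvh"][img]
            row["goal_pass"] = p["goal_pass"][img]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
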