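"""Fully connected regressors for spine displacement and body contour.

Both networks share one architecture — three hidden layers (64-128-64) with
ReLU — and one training regime: Adam (learning rate 1e-3, weight decay
1e-5), MSE loss plus a smoothness penalty on the finite difference of
predictions between z-adjacent slices, and *per-patient* batching (each
optimization step uses all slices of one patient) so intra-patient
correlations along the spinal axis dominate the learned mapping rather than
slice-level noise.

The spine network maps (heart centre, heart→cord vector V) → displacement
ΔV per slice; the body network maps (heart centre, corrected spine vector,
flattened diagnostic-CT polar contour) → the flat-couch contour.

Everything is plain numpy, deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .geometry import (
    CordTrajectory,
    DisplacementField,
    HeartAnchor,
    PolarContour,
    SpineVectorSet,
)

CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class MLPSpec:
    input_dim: int
    output_dim: int
    hidden_sizes: tuple[int, ...] = (64, 128, 64)

    def __post_init__(self):
        if self.input_dim < 1 or self.output_dim < 1:
            raise ValueError("dims must be >= 1")


@dataclass
class TrainConfig:
    """Optimizer and regularization settings.

    ``smoothness_lambda`` weights the mean squared finite difference of the
    (normalized) predictions between z-adjacent slices within a patient,
    discouraging abrupt spatial changes in the learned transformation.
    """

    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    smoothness_lambda: float = 0.01
    epochs: int = 2000
    plateau_patience: int = 200
    plateau_rtol: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0 or self.smoothness_lambda < 0:
            raise ValueError("regularization weights must be >= 0")


@dataclass
class TrainingReport:
    loss_curve: np.ndarray  # per-epoch mean training loss
    final_mae_per_dim: np.ndarray  # mm, per output dimension
    final_mae_vector: float  # mm, mean Euclidean-norm error
    seed: int
    n_patients: int


def _standardize_stats(
    X: np.ndarray, fallback: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean/sd; degenerate (constant) features get ``fallback``.

    Output features use a tiny fallback so a constant target is reproduced
    (almost) exactly and predictions stay invariant to affine unit rescaling
    of the raw data.
    """
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-8, fallback, sd)
    return mean, sd


class TrainedModel:
    """An MLP with frozen weights and input/output normalization stats."""

    def __init__(self, spec: MLPSpec, rng: np.random.Generator):
        self.spec = spec
        sizes = (spec.input_dim, *spec.hidden_sizes, spec.output_dim)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.W.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.b.append(rng.uniform(-bound, bound, size=fan_out))
        self.in_mean = np.zeros(spec.input_dim)
        self.in_sd = np.ones(spec.input_dim)
        self.out_mean = np.zeros(spec.output_dim)
        self.out_sd = np.ones(spec.output_dim)

    # -- forward/backward in normalized space --------------------------------
    def _forward(self, Xn: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [Xn]
        h = Xn
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return h, acts

    def _backward(self, acts: list[np.ndarray], grad_out: np.ndarray):
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        g = grad_out
        for i in range(len(self.W) - 1, -1, -1):
            if i < len(self.W) - 1:
                g = g * (acts[i + 1] > 0)
            gW[i] = acts[i].T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return gW, gb

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass on raw (physical-unit) inputs."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"input dim {X.shape[1]} does not match model "
                f"({self.spec.input_dim})"
            )
        Xn = (X - self.in_mean) / self.in_sd
        Yn, _ = self._forward(Xn)
        return Yn * self.out_sd + self.out_mean

    # -- checkpoint -----------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": CHECKPOINT_SCHEMA,
            "spec": {
                "input_dim": self.spec.input_dim,
                "output_dim": self.spec.output_dim,
                "hidden_sizes": list(self.spec.hidden_sizes),
            },
            "W": [w.tolist() for w in self.W],
            "b": [b.tolist() for b in self.b],
            "in_mean": self.in_mean.tolist(),
            "in_sd": self.in_sd.tolist(),
            "out_mean": self.out_mean.tolist(),
            "out_sd": self.out_sd.tolist(),
            "angles": (
                getattr(self, "angles").tolist()
                if getattr(self, "angles", None) is not None
                else None
            ),
        }

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        if d.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {d.get('schema')}")
        spec = MLPSpec(
            d["spec"]["input_dim"],
            d["spec"]["output_dim"],
            tuple(d["spec"]["hidden_sizes"]),
        )
        m = cls(spec, np.random.default_rng(0))
        m.W = [np.asarray(w, float) for w in d["W"]]
        m.b = [np.asarray(b, float) for b in d["b"]]
        m.in_mean = np.asarray(d["in_mean"], float)
        m.in_sd = np.asarray(d["in_sd"], float)
        m.out_mean = np.asarray(d["out_mean"], float)
        m.out_sd = np.asarray(d["out_sd"], float)
        if d.get("angles") is not None:
            m.angles = np.asarray(d["angles"], float)  # type: ignore[attr-defined]
        return m

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as f:
            return cls.from_dict(json.load(f))


def _train(
    batches: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
) -> tuple[TrainedModel, TrainingReport]:
    """Adam training with per-patient batches and smoothness penalty.

    ``batches`` holds one (X, Y) pair per patient, rows ordered by z.
    """
    if len(batches) < 2:
        raise ValueError("at least 2 patients required for training")
    for X, Y in batches:
        if X.shape[0] < 5:
            raise ValueError("every patient needs at least 5 matched slices")

    rng = np.random.default_rng(config.seed)
    Xall = np.vstack([b[0] for b in batches])
    Yall = np.vstack([b[1] for b in batches])
    spec = MLPSpec(Xall.shape[1], Yall.shape[1])
    model = TrainedModel(spec, rng)
    model.in_mean, model.in_sd = _standardize_stats(Xall)
    model.out_mean, model.out_sd = _standardize_stats(Yall, fallback=1e-6)

    norm = [
        (
            (X - model.in_mean) / model.in_sd,
            (Y - model.out_mean) / model.out_sd,
        )
        for X, Y in batches
    ]

    # Adam state
    mW = [np.zeros_like(w) for w in model.W]
    vW = [np.zeros_like(w) for w in model.W]
    mb = [np.zeros_like(b) for b in model.b]
    vb = [np.zeros_like(b) for b in model.b]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    lam = config.smoothness_lambda

    losses = np.empty(config.epochs)
    best = np.inf
    best_epoch = 0
    n_epochs = config.epochs
    for epoch in range(config.epochs):
        epoch_loss = 0.0
        for Xn, Yn in norm:
            pred, acts = model._forward(Xn)
            resid = pred - Yn
            n, dout = resid.shape
            mse = float(np.mean(resid**2))
            grad = 2.0 * resid / (n * dout)
            loss = mse
            if lam > 0 and n > 1:
                diff = pred[1:] - pred[:-1]
                loss += lam * float(np.mean(diff**2))
                gdiff = 2.0 * lam * diff / ((n - 1) * dout)
                gsmooth = np.zeros_like(pred)
                gsmooth[1:] += gdiff
                gsmooth[:-1] -= gdiff
                grad = grad + gsmooth
            gW, gb = model._backward(acts, grad)
            t += 1
            for i in range(len(model.W)):
                gW[i] += config.weight_decay * model.W[i]
                mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
                vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
                mhat = mW[i] / (1 - beta1**t)
                vhat = vW[i] / (1 - beta2**t)
                model.W[i] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
                mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
                vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
                mhat = mb[i] / (1 - beta1**t)
                vhat = vb[i] / (1 - beta2**t)
                model.b[i] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_loss += loss
        epoch_loss /= len(norm)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}: {epoch_loss}"
            )
        losses[epoch] = epoch_loss
        if epoch_loss < best * (1 - config.plateau_rtol):
            best = epoch_loss
            best_epoch = epoch
        elif epoch - best_epoch >= config.plateau_patience:
            n_epochs = epoch + 1
            break
    losses = losses[:n_epochs]

    pred = model.predict(Xall)
    err = pred - Yall
    mae_dim = np.mean(np.abs(err), axis=0)
    mae_vec = float(np.mean(np.linalg.norm(err, axis=1)))
    report = TrainingReport(
        loss_curve=losses,
        final_mae_per_dim=mae_dim,
        final_mae_vector=mae_vec,
        seed=config.seed,
        n_patients=len(batches),
    )
    return model, report


# ---------------------------------------------------------------------------
# spine displacement network
# ---------------------------------------------------------------------------


@dataclass
class SpinePatient:
    """Training example: one patient's heart anchor and matched spine vectors."""

    heart: HeartAnchor
    vectors: SpineVectorSet


def _spine_features(heart: HeartAnchor, vectors: SpineVectorSet) -> np.ndarray:
    h = heart.center.as_array()
    n = vectors.V.shape[0]
    return np.hstack([np.tile(h, (n, 1)), vectors.V])


def train_spine_model(
    cohort: list[SpinePatient], config: TrainConfig
) -> tuple[TrainedModel, TrainingReport]:
    """Learn per-slice ΔV from (heart centre, V)."""
    batches = []
    for p in cohort:
        if p.vectors.dV is None:
            raise ValueError("spine training requires matched dV")
        batches.append((_spine_features(p.heart, p.vectors), p.vectors.dV))
    return _train(batches, config)


def predict_spine_displacement(
    model: TrainedModel, heart: HeartAnchor, vectors: SpineVectorSet
) -> DisplacementField:
    X = _spine_features(heart, vectors)
    d = model.predict(X)
    return DisplacementField(z=vectors.z.copy(), d=d)


# ---------------------------------------------------------------------------
# body contour network
# ---------------------------------------------------------------------------


@dataclass
class BodySlice:
    """One axial slice of body-network training data."""

    z: float
    corrected_vector: np.ndarray  # V + ΔV, 3-vector mm
    contour_d: PolarContour
    contour_s: PolarContour | None = None


@dataclass
class BodyPatient:
    heart: HeartAnchor
    slices: list[BodySlice]


def _body_features(heart: HeartAnchor, sl: BodySlice) -> np.ndarray:
    return np.concatenate(
        [heart.center.as_array(), np.asarray(sl.corrected_vector, float),
         sl.contour_d.offsets.ravel()]
    )


def train_body_model(
    cohort: list[BodyPatient], config: TrainConfig
) -> tuple[TrainedModel, TrainingReport]:
    """Learn the flat-couch contour from the diagnostic-CT contour, slice-wise."""
    ref_angles = None
    batches = []
    for p in cohort:
        X, Y = [], []
        for sl in sorted(p.slices, key=lambda s: s.z):
            if sl.contour_s is None:
                raise ValueError("body training requires paired sCT contours")
            if ref_angles is None:
                ref_angles = sl.contour_d.angles
            for c in (sl.contour_d, sl.contour_s):
                if c.angles.shape != ref_angles.shape or not np.allclose(
                    c.angles, ref_angles
                ):
                    raise ValueError("inconsistent angle grids across patients")
            X.append(_body_features(p.heart, sl))
            Y.append(sl.contour_s.offsets.ravel())
        batches.append((np.array(X), np.array(Y)))
    model, report = _train(batches, config)
    model.angles = ref_angles.copy()  # type: ignore[attr-defined]
    return model, report


def predict_body_contour(
    model: TrainedModel,
    heart: HeartAnchor,
    corrected_vector: np.ndarray,
    contour_d: PolarContour,
) -> PolarContour:
    angles = getattr(model, "angles", None)
    if angles is not None and (
        contour_d.angles.shape != angles.shape
        or not np.allclose(contour_d.angles, angles)
    ):
        raise ValueError("angle grid does not match training grid")
    sl = BodySlice(z=0.0, corrected_vector=corrected_vector, contour_d=contour_d)
    X = _body_features(heart, sl)
    off = model.predict(X)[0].reshape(-1, 2)
    return PolarContour(angles=contour_d.angles.copy(), offsets=off)
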