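"""Linear SVM decoding: training, decision values, output drift correction.

Three binary contrasts are decoded from multivoxel patterns: rest vs
LGO, rest vs RGO (these two drive the feedback), and LGO vs RGO (an
offline measure of how separable the two imagery tasks became).  Models
are soft-margin linear SVMs minimising ``0.5 * ||w||^2 + c * sum(hinge)``
with c = 1.

The decision trace — w.x + b per volume — can itself drift over a run
(classifier drift); a cumulative linear detrend that re-adds the running
mean removes the linear drift component while preserving the level
information that separates the classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .preprocess import DetrendState, unmask
from .protocol import Condition

__all__ = [
    "LinearModel",
    "DecisionTrace",
    "Contrast",
    "CONTRASTS",
    "train_linear_svm",
    "train_contrast",
    "decision_value",
    "DecisionDetrender",
    "detrend_decisions",
    "weight_map",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class Contrast:
    """A binary classification problem between two conditions."""

    positive: Condition
    negative: Condition

    @property
    def name(self) -> str:
        return f"{self.negative.value}_vs_{self.positive.value}"

    def __str__(self) -> str:
        return self.name


#: the three contrasts evaluated in the study, keyed by short name
CONTRASTS: dict[str, Contrast] = {
    "R_vs_LGO": Contrast(Condition.LGO, Condition.REST),
    "R_vs_RGO": Contrast(Condition.RGO, Condition.REST),
    "LGO_vs_RGO": Contrast(Condition.LGO, Condition.RGO),
}


@dataclass(frozen=True)
class LinearModel:
    """Trained linear decision rule for one binary contrast.

    Predicts ``positive_class`` when ``w.x + b > 0``; a decision value
    of exactly 0 resolves to the negative class (conservative: no
    feedback reward on a tie).
    """

    weights: np.ndarray
    bias: float
    positive_class: Condition
    negative_class: Condition
    c: float = 1.0

    @property
    def contrast(self) -> Contrast:
        return Contrast(self.positive_class, self.negative_class)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """w.x + b for each column of a features x samples matrix."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] != self.weights.shape[0]:
            raise ValueError(
                f"feature count {X.shape[0]} does not match model "
                f"({self.weights.shape[0]} weights)"
            )
        return self.weights @ X + self.bias

    def predict(self, decision_vals: np.ndarray) -> np.ndarray:
        """Threshold decision values at 0 (ties -> negative class)."""
        vals = np.atleast_1d(np.asarray(decision_vals))
        out = np.empty(vals.shape, dtype=object)
        out[:] = self.negative_class
        out[vals > 0] = self.positive_class
        return out


@dataclass
class DecisionTrace:
    """Per-volume classifier outputs for one run and one contrast."""

    raw: np.ndarray  # raw decision values w.x + b
    corrected: np.ndarray  # drift-corrected decision values
    predicted: np.ndarray  # predicted Condition per volume
    volume_indices: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.raw)
        if not (len(self.corrected) == len(self.predicted) == len(self.volume_indices) == n):
            raise ValueError("trace sequences must share length")


def train_linear_svm(
    X: np.ndarray,
    y: Sequence[Condition] | np.ndarray,
    positive_class: Condition,
    negative_class: Condition,
    c: float = 1.0,
) -> LinearModel:
    """Train a soft-margin linear SVM on a features x samples matrix.

    Minimises ``0.5 * ||w||^2 + c * sum_i max(0, 1 - y_i (w.x_i + b))``
    (the study's LIBSVM formulation with default c = 1), via the exact
    dual solver.
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in training features")
    y = np.asarray(y, dtype=object)
    if X.shape[1] != y.shape[0]:
        raise ValueError(
            f"sample count mismatch: X has {X.shape[1]} columns, "
            f"y has {y.shape[0]} labels"
        )
    signs = np.where(y == positive_class, 1.0, np.where(y == negative_class, -1.0, 0.0))
    if np.any(signs == 0):
        bad = set(y[signs == 0])
        raise ValueError(f"labels {bad} belong to neither class of the contrast")
    if len(np.unique(signs)) < 2:
        raise ValueError("training data must contain both classes")

    svc = SVC(kernel="linear", C=c, tol=1e-8, shrinking=False)
    svc.fit(X.T, signs)
    w = svc.coef_.ravel().copy()
    b = float(svc.intercept_[0])
    return LinearModel(
        weights=w,
        bias=b,
        positive_class=positive_class,
        negative_class=negative_class,
        c=c,
    )


def train_contrast(
    X: np.ndarray,
    labels: np.ndarray,
    contrast: Contrast,
    c: float = 1.0,
) -> LinearModel:
    """Train one contrast, keeping only the volumes of its two conditions."""
    labels = np.asarray(labels, dtype=object)
    keep = (labels == contrast.positive) | (labels == contrast.negative)
    return train_linear_svm(
        np.asarray(X)[:, keep], labels[keep], contrast.positive, contrast.negative, c
    )


def decision_value(model: LinearModel, x: np.ndarray) -> float:
    """w.x + b for a single feature vector."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != model.weights.shape:
        raise ValueError(
            f"feature vector shape {x.shape} does not match weights "
            f"{model.weights.shape}"
        )
    return float(model.weights @ x + model.bias)


class DecisionDetrender:
    """Streaming drift correction for a scalar decision-value sequence.

    Applies the cumulative linear detrend to the raw values and re-adds
    the cumulative mean, so only the fitted linear drift is removed and
    the class-separating level survives.  During warm-up (n <= 2) the
    residual is 0, so the corrected value equals the running mean — for
    a single value, the value itself.

    ``warmup`` postpones the correction entirely: the first ``warmup``
    values pass through raw.  Early in a run the line fit to the
    decision sequence cannot tell drift from the task's block structure
    and would cancel genuine class separation; the closed-loop session
    sets a warm-up spanning the first rest-task-rest cycle.
    """

    def __init__(self, window: int | None = None, warmup: int = 0):
        self._state = DetrendState(1, window=window)
        self.warmup = warmup
        self._sum = 0.0
        self._n = 0

    def step(self, value: float, t: float | None = None) -> float:
        """Ingest a decision value (optionally at explicit time t); correct it."""
        resid = self._state.update(np.asarray([value], dtype=np.float64), t=t)[0]
        self._sum += float(value)
        self._n += 1
        if self._n <= self.warmup:
            return float(value)
        return resid + self._sum / self._n

    def correct(self, value: float, t: float) -> float:
        """Correct a decision value against the current fit without ingesting.

        Used for task-cue volumes in the closed loop, whose decision
        values carry class signal the drift line must not absorb.
        """
        if self._n == 0 or self._n <= self.warmup:
            return float(value)
        resid = self._state.evaluate(np.asarray([value], dtype=np.float64), t)[0]
        return resid + self._sum / self._n

    def reset(self) -> None:
        self._state.reset()
        self._sum = 0.0
        self._n = 0


def detrend_decisions(
    raw: np.ndarray, model: LinearModel, window: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Drift-correct a raw decision-value sequence; re-threshold at 0.

    Returns ``(corrected_values, predicted_labels)``.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size < 1:
        raise ValueError("need at least one decision value")
    d = DecisionDetrender(window=window)
    corrected = np.array([d.step(v) for v in raw])
    return corrected, model.predict(corrected)


def weight_map(model: LinearModel, mask: np.ndarray) -> np.ndarray:
    """Scatter model weights back into image space (out-of-mask = 0)."""
    return unmask(model.weights, mask)


# -- serialisation ----------------------------------------------------------


def save_model(model: LinearModel, path_prefix: str | Path) -> None:
    """Save as ``<prefix>.json`` (metadata) + ``<prefix>.npy`` (weights)."""
    prefix = Path(path_prefix)
    np.save(prefix.with_suffix(".npy"), model.weights)
    meta = {
        "bias": model.bias,
        "positive_class": model.positive_class.value,
        "negative_class": model.negative_class.value,
        "c": model.c,
        "n_features": int(model.weights.shape[0]),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_model(path_prefix: str | Path) -> LinearModel:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    weights = np.load(prefix.with_suffix(".npy"))
    if weights.shape[0] != meta["n_features"]:
        raise ValueError("weight file does not match metadata")
    return LinearModel(
        weights=weights,
        bias=meta["bias"],
        positive_class=Condition(meta["positive_class"]),
        negative_class=Condition(meta["negative_class"]),
        c=meta["c"],
    )
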