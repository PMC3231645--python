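"""Membership estimation with a 3-5-3 back-propagation network.

Each factor category (shape, texture, colour) gets its own small
feed-forward network: three inputs (the category's features, min-max
scaled to [0, 1] on the training set), five logistic hidden units, and
three logistic outputs, one per grade.  Training is plain online gradient
descent on squared error against one-hot targets, repeated until every
training example is classified correctly (argmax over outputs, with a
small required winning margin so the stopping rule is never decided by a
tie) or a maximum epoch count is reached.

At evaluation time the raw outputs are renormalised to sum to one, giving
a membership row over the grades.  Because the network consumes the three
category features jointly while the evaluation matrix needs one membership
row *per individual feature*, each sub-factor's row is produced by
class-conditional probing: the membership of feature value u_j in grade c
is the net's output for c with input j set to u_j and the other two inputs
clamped at grade c's own training means -- "how strongly would the net
support c if the rest of the category looked typical for c?"  Probing all
classes at the *global* training mean instead was tried and rejected: any
grade occupying the middle of feature space wins every mid-space probe,
regardless of the observed feature (see :func:`build_R`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateDataError,
    NumericalError,
    ParameterError,
)

N_INPUT, N_HIDDEN, N_OUTPUT = 3, 5, 3


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class TrainConfig:
    """Hyper-parameters of the back-propagation training loop."""

    learning_rate: float = 0.5
    max_epochs: int = 5000
    #: required winning margin of the true-class output in the stopping
    #: check; ties (margin 0) always count as incorrect.  A substantial
    #: margin keeps training until the outputs approach the one-hot
    #: targets, which is what calibrates the memberships.
    target_margin: float = 0.3

    def __post_init__(self) -> None:
        if not (self.learning_rate > 0):
            raise ParameterError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ParameterError("max_epochs must be >= 1")
        if not (0 < self.target_margin < 0.5):
            raise ParameterError("target_margin must lie in (0, 0.5)")


@dataclass
class MLPParams:
    """Weights, input scaling and class order of one trained category net."""

    w_hidden: np.ndarray  # (5, 3)
    b_hidden: np.ndarray  # (5,)
    w_out: np.ndarray     # (3, 5)
    b_out: np.ndarray     # (3,)
    classes: tuple[str, ...]
    feature_min: np.ndarray  # (3,)
    feature_max: np.ndarray  # (3,)
    #: per-class training means in scaled space, (n_classes, 3)
    class_means_scaled: np.ndarray
    seed: int = 0
    converged: bool = True

    def scale(self, features: np.ndarray) -> np.ndarray:
        """Min-max scale raw features to [0, 1]; outside values clip."""
        span = np.where(self.feature_max > self.feature_min,
                        self.feature_max - self.feature_min, 1.0)
        return np.clip((np.asarray(features, dtype=np.float64)
                        - self.feature_min) / span, 0.0, 1.0)

    def forward(self, scaled: np.ndarray) -> np.ndarray:
        """Raw network outputs in (0, 1) for scaled inputs (..., 3)."""
        h = _sigmoid(scaled @ self.w_hidden.T + self.b_hidden)
        return _sigmoid(h @ self.w_out.T + self.b_out)

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out.tolist(),
            "classes": list(self.classes),
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "class_means_scaled": self.class_means_scaled.tolist(),
            "seed": self.seed,
            "converged": self.converged,
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MLPParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        obj = json.loads(text)
        return cls(
            w_hidden=np.asarray(obj["w_hidden"], dtype=np.float64),
            b_hidden=np.asarray(obj["b_hidden"], dtype=np.float64),
            w_out=np.asarray(obj["w_out"], dtype=np.float64),
            b_out=np.asarray(obj["b_out"], dtype=np.float64),
            classes=tuple(obj["classes"]),
            feature_min=np.asarray(obj["feature_min"], dtype=np.float64),
            feature_max=np.asarray(obj["feature_max"], dtype=np.float64),
            class_means_scaled=np.asarray(obj["class_means_scaled"],
                                          dtype=np.float64),
            seed=int(obj["seed"]),
            converged=bool(obj["converged"]),
        )


@dataclass
class MembershipMatrix:
    """Per-category membership rows: features x classes, rows sum to one."""

    entries: np.ndarray
    category: str
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.float64)
        if self.entries.ndim != 2:
            raise ParameterError("entries must be a 2-D matrix")
        if self.entries.shape[1] != len(self.classes):
            raise ParameterError("one column per class is required")
        if np.any(self.entries < 0) or np.any(self.entries > 1):
            raise ParameterError("memberships must lie in [0, 1]")
        sums = self.entries.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ParameterError(
                f"membership rows must sum to 1; got row sums {sums}"
            )


def _all_correct(outputs: np.ndarray, targets_idx: np.ndarray,
                 margin: float) -> bool:
    """Stopping check: true output beats every other by at least margin."""
    true_vals = outputs[np.arange(len(outputs)), targets_idx]
    masked = outputs.copy()
    masked[np.arange(len(outputs)), targets_idx] = -np.inf
    runner_up = masked.max(axis=1)
    return bool(np.all(true_vals - runner_up >= margin))


def train_category_net(features: np.ndarray, labels: list[str] | np.ndarray,
                       config: TrainConfig | None = None, seed: int = 0,
                       classes: tuple[str, ...] | None = None) -> MLPParams:
    """Train one category net on labelled 3-feature examples.

    Online gradient descent on squared error with one-hot targets, in the
    given data order (no shuffling), initial weights uniform(-0.5, 0.5)
    from ``seed``; bit-reproducible.  Stops once every training example is
    classified correctly, else at ``max_epochs`` with a warning.
    """
    if config is None:
        config = TrainConfig()
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != N_INPUT:
        raise DataError(f"features must be (n, {N_INPUT}); got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise DataError("features contain non-finite values")
    labels = list(labels)
    if len(labels) != len(X):
        raise DataError("labels and features differ in length")
    if classes is None:
        classes = tuple(dict.fromkeys(labels))  # order of first appearance
    if len(set(labels)) < 2 or not set(labels) <= set(classes):
        raise DegenerateDataError(
            f"training data must contain >= 2 of the classes {classes}"
        )
    if len(classes) != N_OUTPUT:
        raise DegenerateDataError(
            f"exactly {N_OUTPUT} classes are required; got {classes}"
        )
    class_idx = {c: k for k, c in enumerate(classes)}
    t_idx = np.array([class_idx[l] for l in labels])
    targets = np.eye(N_OUTPUT)[t_idx]

    fmin = X.min(axis=0)
    fmax = X.max(axis=0)
    span = np.where(fmax > fmin, fmax - fmin, 1.0)
    Xs = (X - fmin) / span

    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-0.5, 0.5, (N_HIDDEN, N_INPUT))
    b1 = rng.uniform(-0.5, 0.5, N_HIDDEN)
    W2 = rng.uniform(-0.5, 0.5, (N_OUTPUT, N_HIDDEN))
    b2 = rng.uniform(-0.5, 0.5, N_OUTPUT)
    lr = config.learning_rate
    converged = False
    for _ in range(config.max_epochs):
        for x, t in zip(Xs, targets):
            h = _sigmoid(W1 @ x + b1)
            o = _sigmoid(W2 @ h + b2)
            delta_o = (o - t) * o * (1.0 - o)
            delta_h = (W2.T @ delta_o) * h * (1.0 - h)
            W2 -= lr * np.outer(delta_o, h)
            b2 -= lr * delta_o
            W1 -= lr * np.outer(delta_h, x)
            b1 -= lr * delta_h
        out = _sigmoid(_sigmoid(Xs @ W1.T + b1) @ W2.T + b2)
        if _all_correct(out, t_idx, config.target_margin):
            converged = True
            break
    if not converged:
        warnings.warn(
            "training reached max_epochs without classifying every "
            "example correctly", stacklevel=2)
    return MLPParams(
        w_hidden=W1, b_hidden=b1, w_out=W2, b_out=b2, classes=classes,
        feature_min=fmin, feature_max=fmax,
        class_means_scaled=np.vstack([
            Xs[t_idx == k].mean(axis=0) if np.any(t_idx == k)
            else Xs.mean(axis=0)
            for k in range(N_OUTPUT)]),
        seed=int(seed), converged=converged,
    )


def predict_membership(params: MLPParams,
                       features: np.ndarray) -> np.ndarray:
    """Membership vector over the classes for one raw 3-feature input.

    The network outputs are divided by their sum, so the result is a
    probability-like vector summing to one.
    """
    out = params.forward(params.scale(np.asarray(features, float)))
    s = float(out.sum())
    if s < 1e-12:
        raise NumericalError("all network outputs are (numerically) zero")
    return out / s


def build_R(features9, nets: dict[str, MLPParams]) -> list[MembershipMatrix]:
    """Build the three sub-factor evaluation matrices from nine features.

    For category i with features (u1, u2, u3), entry (j, c) of R_i is the
    net's class-c output with input j at its observed (scaled) value and
    the other two inputs clamped at class c's own training means; each row
    is then renormalised to sum to one.  This reads the net as a
    compatibility oracle -- "how strongly is grade c supported when
    feature j looks like this and the rest of the category is typical for
    c?" -- and keeps the nine rows distinct and informative even when one
    grade sits between the others in feature space.

    ``features9`` is a :class:`~leafgrade.pipeline.FeatureVector` or any
    object with ``category(name) -> 3 array``; ``nets`` maps category
    names to trained :class:`MLPParams`.
    """
    matrices = []
    for cat in getattr(features9, "categories", ("shape", "texture", "color")):
        if cat not in nets:
            raise ConfigurationError(f"no trained net for category {cat!r}")
        params = nets[cat]
        scaled = params.scale(features9.category(cat))
        rows = []
        for j in range(N_INPUT):
            row = np.empty(N_OUTPUT)
            for c in range(N_OUTPUT):
                probe = params.class_means_scaled[c].copy()
                probe[j] = scaled[j]
                row[c] = params.forward(probe)[c]
            s = float(row.sum())
            if s < 1e-12:
                raise NumericalError("all network outputs are zero")
            rows.append(row / s)
        matrices.append(MembershipMatrix(entries=np.array(rows),
                                         category=cat,
                                         classes=params.classes))
    return matrices
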