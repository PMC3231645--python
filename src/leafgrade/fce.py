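"""Two-level fuzzy comprehensive evaluation (FCE).

Grading combines nine membership grades hierarchically.  Within each
factor category i, the sub-factor weight vector A_i composes the
membership matrix R_i (features x classes) into a one-level evaluation
vector

    B_i = A_i . R_i            (weighted-average composition)

and across categories the category weight vector A composes the stacked
one-level vectors B into the two-level evaluation vector

    V = A . B,    V_normalised = V / sum(V),

with the decided grade the argmax of V.  The composition operator is the
weighted average M(., +): with unit-sum weights and unit-sum membership
rows it conserves total mass, so every B_i and V sums to one.  Max-min
composition is deliberately not used; it does not reproduce hand-checked
worked evaluations, while the weighted average does.

The shipped default weights are A = (0.35, 0.2, 0.45) over (shape,
texture, colour) -- colour carries the most grading information, texture
the least -- and A1 = (0.3, 0.4, 0.3), A2 = (0.4, 0.3, 0.3),
A3 = (0.3, 0.3, 0.4) over the sub-factors.  Any number of categories and
classes >= 2 is supported; the 3 x 3 x 3 layout is just the default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, NumericalError, ParameterError
from .membership import MembershipMatrix, MLPParams, build_R

DEFAULT_CLASSES = ("X1L", "B4L", "S1")
DEFAULT_CATEGORIES = ("shape", "texture", "color")


def _check_weights(w: np.ndarray, name: str) -> np.ndarray:
    w = np.asarray(w, dtype=np.float64)
    if w.ndim != 1 or len(w) < 2:
        raise ParameterError(f"{name} must be a vector of >= 2 weights")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ParameterError(
            f"{name} must be nonnegative and sum to 1; got {w}"
        )
    return w


@dataclass
class WeightConfig:
    """Category weights A and per-category sub-factor weights A_i."""

    category_weights: np.ndarray
    feature_weights: list[np.ndarray]
    categories: tuple[str, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        self.category_weights = _check_weights(self.category_weights, "A")
        if len(self.feature_weights) != len(self.category_weights):
            raise ConfigurationError(
                "one sub-factor weight vector per category is required"
            )
        self.feature_weights = [
            _check_weights(a, f"A{i + 1}")
            for i, a in enumerate(self.feature_weights)
        ]

    @classmethod
    def default(cls) -> "WeightConfig":
        return cls(
            category_weights=np.array([0.35, 0.2, 0.45]),
            feature_weights=[np.array([0.3, 0.4, 0.3]),
                             np.array([0.4, 0.3, 0.3]),
                             np.array([0.3, 0.3, 0.4])],
        )

    @classmethod
    def from_dict(cls, obj: dict) -> "WeightConfig":
        try:
            w = obj["weights"] if "weights" in obj else obj
            sub = [np.asarray(w[f"A{i + 1}"], dtype=float)
                   for i in range(len(w["A"]))]
            return cls(category_weights=np.asarray(w["A"], dtype=float),
                       feature_weights=sub,
                       categories=tuple(w.get("categories",
                                              DEFAULT_CATEGORIES)))
        except KeyError as exc:
            raise ConfigurationError(f"missing weight entry: {exc}") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "WeightConfig":
        text = Path(path).read_text()
        obj = yaml.safe_load(text)
        if not isinstance(obj, dict):
            raise ConfigurationError(f"cannot parse weights from {path}")
        return cls.from_dict(obj)

    def to_dict(self) -> dict:
        return {"weights": {
            "A": self.category_weights.tolist(),
            **{f"A{i + 1}": a.tolist()
               for i, a in enumerate(self.feature_weights)},
            "categories": list(self.categories),
        }}


@dataclass
class FCEResult:
    """All intermediates of one two-level evaluation, for audit."""

    B: np.ndarray                       # (m categories, n classes)
    V: np.ndarray                       # (n,)
    V_normalized: np.ndarray            # (n,), sums to 1
    label: str
    memberships: dict[str, float]
    R: list[MembershipMatrix] | None = None
    classes: tuple[str, ...] = DEFAULT_CLASSES

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "B": np.round(self.B, 10).tolist(),
            "V": np.round(self.V, 10).tolist(),
            "V_normalized": np.round(self.V_normalized, 10).tolist(),
            "label": self.label,
            "memberships": self.memberships,
            "classes": list(self.classes),
        }
        if self.R is not None:
            obj["R"] = [{"category": r.category,
                         "entries": r.entries.tolist()} for r in self.R]
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def one_level(A_i: np.ndarray, R_i: MembershipMatrix | np.ndarray
              ) -> np.ndarray:
    """One-level composition B_i = A_i . R_i (weighted column average)."""
    A_i = np.asarray(A_i, dtype=np.float64)
    M = R_i.entries if isinstance(R_i, MembershipMatrix) else np.asarray(
        R_i, dtype=np.float64)
    if M.ndim != 2 or len(A_i) != M.shape[0]:
        raise ParameterError(
            f"weight length {len(A_i)} does not match matrix rows {M.shape}"
        )
    return A_i @ M


def two_level(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Two-level composition V = A . B across the category vectors."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if B.ndim != 2 or len(A) != B.shape[0]:
        raise ParameterError(
            f"weight length {len(A)} does not match B rows {B.shape}"
        )
    return A @ B


def normalize_v(V: np.ndarray) -> np.ndarray:
    """Divide V by its sum so the components sum to one."""
    V = np.asarray(V, dtype=np.float64)
    s = float(V.sum())
    if s <= 0:
        raise NumericalError(f"evaluation vector sums to {s}; cannot normalise")
    return V / s


def decide_class(V: np.ndarray,
                 classes: tuple[str, ...] = DEFAULT_CLASSES
                 ) -> tuple[str, dict[str, float]]:
    """Pick the class of the maximal component of (normalised) V.

    Ties are broken in favour of the earliest class in ``classes`` and
    reported with a warning.
    """
    V = np.asarray(V, dtype=np.float64)
    if len(V) != len(classes):
        raise ParameterError("one component per class is required")
    top = int(np.argmax(V))
    if np.count_nonzero(V == V[top]) > 1:
        warnings.warn("tie in evaluation vector; using declared class order",
                      stacklevel=2)
    return classes[top], {c: float(v) for c, v in zip(classes, V)}


def evaluate_matrices(R_list: list[MembershipMatrix] | list[np.ndarray],
                      weights: WeightConfig | None = None,
                      classes: tuple[str, ...] | None = None) -> FCEResult:
    """Run the full two-level evaluation on given membership matrices."""
    if weights is None:
        weights = WeightConfig.default()
    if len(R_list) != len(weights.feature_weights):
        raise ConfigurationError(
            "one membership matrix per category is required"
        )
    if classes is None:
        first = R_list[0]
        classes = (first.classes if isinstance(first, MembershipMatrix)
                   else DEFAULT_CLASSES)
    B = np.vstack([one_level(a, r)
                   for a, r in zip(weights.feature_weights, R_list)])
    V = two_level(weights.category_weights, B)
    Vn = normalize_v(V)
    label, memberships = decide_class(Vn, classes)
    kept = [r for r in R_list if isinstance(r, MembershipMatrix)] or None
    return FCEResult(B=B, V=V, V_normalized=Vn, label=label,
                     memberships=memberships, R=kept, classes=classes)


def grade_leaf(features9, nets: dict[str, MLPParams],
               weights: WeightConfig | None = None) -> FCEResult:
    """Grade one leaf from its nine features via the trained nets and FCE."""
    R_list = build_R(features9, nets)
    classes = R_list[0].classes
    return evaluate_matrices(R_list, weights, classes)
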