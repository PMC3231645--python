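"""End-to-end grading pipeline and experiment harness.

``extract_features`` turns one leaf image into the nine-feature record the
grader consumes.  ``run_experiment`` mirrors the original study design on
synthetic data: generate a class-balanced set of leaves, extract features,
train the three category membership nets on one group, then grade both the
trained group and a held-out group with the two-level fuzzy comprehensive
evaluation and report accuracies.  ``demo_worked_example`` replays the
published worked evaluation from the fixture membership table.

All randomness flows from a single top-level seed through named
substreams (generation, network initialisation), so any report is exactly
reproducible from its configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fixtures
from .color import rgb_variance
from .edges import EdgeConfig, LeafImage, binarize, extract_contour
from .errors import ConfigurationError, LeafGradeError
from .fce import FCEResult, WeightConfig, evaluate_matrices, grade_leaf
from .membership import MLPParams, TrainConfig, train_category_net
from .shape import (
    DEFAULT_FIT_TOLERANCE,
    fit_polygon,
    shape_features_from_polygon,
)
from .synthetic import (
    DEFAULT_CLASS_SPECS,
    LeafClassSpec,
    derive_seed,
    generate_leaf,
)
from .texture import DEFAULT_OFFSET, texture_features

CATEGORIES = ("shape", "texture", "color")

#: CSV header of a feature table row.
FEATURE_COLUMNS = ("path", "label", "area_px", "perimeter_px",
                   "disfigurement_pct", "energy", "entropy", "contrast",
                   "var_r", "var_g", "var_b")


@dataclass
class FeatureVector:
    """The nine features of one leaf, grouped by factor category."""

    shape: np.ndarray    # area_px, perimeter_px, disfigurement_pct
    texture: np.ndarray  # energy, entropy, contrast
    color: np.ndarray    # var_r, var_g, var_b
    label: str | None = None
    path: str | None = None

    categories = CATEGORIES

    def __post_init__(self) -> None:
        for name in CATEGORIES:
            v = np.asarray(getattr(self, name), dtype=np.float64).ravel()
            if v.shape != (3,):
                raise ConfigurationError(f"{name} must hold 3 features")
            setattr(self, name, v)

    def category(self, name: str) -> np.ndarray:
        if name not in CATEGORIES:
            raise ConfigurationError(f"unknown category {name!r}")
        return getattr(self, name)

    def as_array(self) -> np.ndarray:
        """All nine features in U11..U33 order."""
        return np.concatenate([self.shape, self.texture, self.color])

    def as_row(self) -> dict:
        vals = self.as_array()
        row = dict(zip(FEATURE_COLUMNS[2:], map(float, vals)))
        row["path"] = self.path or ""
        row["label"] = self.label or ""
        return row

    @classmethod
    def from_row(cls, row: dict) -> "FeatureVector":
        vals = [float(row[c]) for c in FEATURE_COLUMNS[2:]]
        return cls(shape=vals[0:3], texture=vals[3:6], color=vals[6:9],
                   label=row.get("label") or None,
                   path=row.get("path") or None)


def extract_features(image: LeafImage, config: EdgeConfig | None = None,
                     fit_tolerance: float = DEFAULT_FIT_TOLERANCE,
                     glcm_offset: tuple[int, int] = DEFAULT_OFFSET,
                     label: str | None = None,
                     glcm_raw: bool = False,
                     entropy_as_printed: bool = False) -> FeatureVector:
    """Measure all nine features of a single-leaf image.

    The leaf mask (used for colour and texture) excludes hole pixels, so
    disfigured regions contribute to the shape features only.
    """
    if config is None:
        config = EdgeConfig()
    mask = binarize(image, config)
    contour = extract_contour(image, config, mask=mask)
    poly = fit_polygon(contour, fit_tolerance)
    sf = shape_features_from_polygon(image, poly)
    tf = texture_features(image, mask, glcm_offset, raw=glcm_raw,
                          entropy_as_printed=entropy_as_printed)
    cf = rgb_variance(image, mask)
    return FeatureVector(shape=sf.as_array(), texture=tf.as_array(),
                         color=cf.as_array(), label=label,
                         path=image.path)


# ---------------------------------------------------------------------------
# experiment harness


@dataclass
class ExperimentConfig:
    """Configuration of one synthetic train-and-grade experiment.

    Counts are per class; the defaults split 100 training and 50 held-out
    leaves as evenly as three balanced classes allow.
    """

    n_train_per_class: tuple[int, ...] = (34, 33, 33)
    n_test_per_class: tuple[int, ...] = (17, 17, 16)
    seed: int = 0
    specs: tuple[LeafClassSpec, ...] = DEFAULT_CLASS_SPECS
    canvas_size: int = 512
    weights: WeightConfig | None = None
    edge_config: EdgeConfig | None = None
    fit_tolerance: float = DEFAULT_FIT_TOLERANCE
    glcm_offset: tuple[int, int] = DEFAULT_OFFSET
    train_config: TrainConfig = field(
        default_factory=lambda: TrainConfig(max_epochs=1500))

    def __post_init__(self) -> None:
        def counts(v):
            if isinstance(v, int):
                return tuple([v] * len(self.specs))
            return tuple(int(x) for x in v)

        self.n_train_per_class = counts(self.n_train_per_class)
        self.n_test_per_class = counts(self.n_test_per_class)
        if len(self.n_train_per_class) != len(self.specs) or \
                len(self.n_test_per_class) != len(self.specs):
            raise ConfigurationError("one count per class is required")
        if min(self.n_train_per_class) < 1 or min(self.n_test_per_class) < 1:
            raise ConfigurationError("all per-class counts must be >= 1")


def _make_group(config: ExperimentConfig, counts: tuple[int, ...],
                stream: int) -> list[tuple[FeatureVector, str]]:
    """Generate one group of leaves and extract features, labelled."""
    out = []
    for ci, (spec, n) in enumerate(zip(config.specs, counts)):
        for j in range(n):
            leaf_seed = derive_seed(config.seed, 1000 * stream + ci, j)
            image, truth = generate_leaf(spec, config.canvas_size, leaf_seed)
            fv = extract_features(image, config.edge_config,
                                  config.fit_tolerance, config.glcm_offset,
                                  label=truth.label)
            out.append((fv, truth.label))
    return out


def train_nets(features: list[FeatureVector], labels: list[str],
               config: TrainConfig | None = None, seed: int = 0,
               classes: tuple[str, ...] | None = None
               ) -> dict[str, MLPParams]:
    """Train one membership net per factor category."""
    if classes is None:
        classes = tuple(dict.fromkeys(labels))
    nets = {}
    for k, cat in enumerate(CATEGORIES):
        X = np.vstack([fv.category(cat) for fv in features])
        nets[cat] = train_category_net(
            X, labels, config, seed=derive_seed(seed, 9000 + k, 0),
            classes=classes)
    return nets


def _grade_group(group, nets, weights) -> dict:
    classes = nets[CATEGORIES[0]].classes
    n_classes = len(classes)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    idx = {c: k for k, c in enumerate(classes)}
    correct = 0
    for fv, label in group:
        result = grade_leaf(fv, nets, weights)
        confusion[idx[label], idx[result.label]] += 1
        correct += int(result.label == label)
    return {
        "n": len(group),
        "accuracy": correct / len(group),
        "confusion": confusion.tolist(),
        "classes": list(classes),
    }


def run_experiment(config: ExperimentConfig | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Generate, extract, train and grade; return an accuracy report.

    The report contains per-group accuracy and confusion matrices plus
    every seed involved; identical configurations produce byte-identical
    reports.  With ``out_dir`` given, ``report.json`` and ``report.md``
    are written there.
    """
    if config is None:
        config = ExperimentConfig()
    stage = "generate/extract training group"
    try:
        train_group = _make_group(config, config.n_train_per_class, stream=1)
        stage = "generate/extract held-out group"
        test_group = _make_group(config, config.n_test_per_class, stream=2)
        stage = "train membership nets"
        feats = [fv for fv, _ in train_group]
        labels = [lab for _, lab in train_group]
        classes = tuple(spec.label for spec in config.specs)
        nets = train_nets(feats, labels, config.train_config,
                          seed=config.seed, classes=classes)
        stage = "grade"
        weights = config.weights or WeightConfig.default()
        report = {
            "seed": config.seed,
            "canvas_size": config.canvas_size,
            "n_train_per_class": list(config.n_train_per_class),
            "n_test_per_class": list(config.n_test_per_class),
            "weights": weights.to_dict(),
            "net_converged": {c: nets[c].converged for c in CATEGORIES},
            "net_seeds": {c: nets[c].seed for c in CATEGORIES},
            "train": _grade_group(train_group, nets, weights),
            "test": _grade_group(test_group, nets, weights),
        }
    except LeafGradeError as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
        (out_dir / "report.md").write_text(_report_markdown(report))
    return report


def _report_markdown(report: dict) -> str:
    lines = ["# Synthetic grading experiment", "",
             f"seed: {report['seed']}",
             f"train leaves per class: {report['n_train_per_class']}",
             f"held-out leaves per class: {report['n_test_per_class']}", ""]
    for group in ("train", "test"):
        g = report[group]
        lines.append(f"## {group} group (n = {g['n']})")
        lines.append(f"accuracy: {g['accuracy']:.3f}")
        lines.append("")
        header = "| true \\ graded | " + " | ".join(g["classes"]) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (len(g["classes"]) + 1))
        for c, row in zip(g["classes"], g["confusion"]):
            lines.append("| " + c + " | "
                         + " | ".join(str(v) for v in row) + " |")
        lines.append("")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# worked example


def demo_worked_example(verbose: bool = True) -> FCEResult:
    """Replay the published worked evaluation from the fixture table.

    Composes the nine fixture membership grades through both FCE levels
    with the default weights and (optionally) prints B, V, normalised V
    and the decided grade, annotated where the recomputed values differ
    from the ones printed in the source table.
    """
    R = fixtures.table6_membership_matrices()
    result = evaluate_matrices(R, WeightConfig.default(),
                               classes=fixtures.CLASSES)
    if verbose:
        printed = fixtures.worked_example_values()
        print("One-level evaluation matrix B (rows: shape, texture, colour):")
        for i, row in enumerate(result.B):
            note = ""
            if not np.allclose(np.round(row, 2), printed["printed_B"][i]):
                note = f"   (printed: {printed['printed_B'][i]})"
            print("  " + "  ".join(f"{v:.2f}" for v in row) + note)
        note = ""
        if not np.allclose(np.round(result.V, 4), printed["printed_V"]):
            note = f"   (printed: {printed['printed_V']})"
        print("Two-level evaluation vector V: "
              + "  ".join(f"{v:.4f}" for v in result.V) + note)
        print("Normalised V: "
              + "  ".join(f"{v:.4f}" for v in result.V_normalized))
        print(f"Decided grade: {result.label}")
    return result
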