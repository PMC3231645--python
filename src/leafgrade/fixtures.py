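"""Reference tables of hand-graded leaves, shipped as package data.

These small tables transcribe published measurements of real graded
tobacco leaves: shape, colour and texture features of sample leaves
(``table1`` .. ``table3``), average features of standard specimens per
grade (``table4``), the features of one test leaf (``table5``), and the
membership grades of that leaf's nine features over the three grades
(``table6``).  They serve two purposes in the test suite: realism
envelopes for the synthetic generator, and the frozen input of the worked
grading example.

Values are stored exactly as printed (strings) and parsed to numbers on
load.  Known internal inconsistencies of the source tables are shipped
verbatim and flagged in ``notes`` -- no reconciliation is attempted.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ConfigurationError
from .membership import MembershipMatrix

FEATURE_ORDER = ("U11", "U12", "U13", "U21", "U22", "U23",
                 "U31", "U32", "U33")
CLASSES = ("X1L", "B4L", "S1")
CATEGORIES = ("shape", "texture", "color")

_FILES = {
    "table1": "table1_shape.csv",
    "table2": "table2_color.csv",
    "table3": "table3_texture.csv",
    "table4": "table4_standard_specimens.csv",
    "table5": "table5_test_leaf.csv",
    "table6": "table6_membership.csv",
    "worked_example": "worked_example.json",
}

_NOTES = {
    "table2": ["colour-feature magnitudes (66-186) differ in scale from the "
               "575-1032 colour entries of table4/table5; the discrepancy is "
               "unexplained in the source and left as is"],
    "table3": ["texture magnitudes cannot be reproduced from the stated "
               "formulas at any obvious normalisation; fixture only, not a "
               "reproduction target"],
    "table4": ["the U11 (area) column holds perimeter-scale numbers and U12 "
               "holds area-scale numbers relative to table1; stored verbatim"],
    "table5": ["same column-scale caveat as table4"],
}


@dataclass
class PaperFixture:
    """One transcribed table: verbatim strings, parsed numbers, caveats."""

    table_id: str
    rows: list[dict]
    notes: list[str] = field(default_factory=list)

    def column(self, name: str) -> np.ndarray:
        return np.array([float(r[name]) for r in self.rows])


def _parse(value: str):
    try:
        f = float(value)
    except ValueError:
        return value
    return f


def load_fixture(table_id: str) -> PaperFixture:
    """Load a transcribed table by id (``table1`` .. ``table6``)."""
    if table_id not in _FILES:
        raise ConfigurationError(
            f"unknown fixture {table_id!r}; known: {sorted(_FILES)}"
        )
    ref = resources.files("leafgrade.data") / _FILES[table_id]
    if table_id == "worked_example":
        obj = json.loads(ref.read_text())
        return PaperFixture(table_id=table_id, rows=[obj],
                            notes=list(obj.get("printed_discrepancy", [])))
    with ref.open() as fh:
        reader = csv.DictReader(fh)
        rows = [{k: _parse(v) for k, v in row.items()} for row in reader]
    return PaperFixture(table_id=table_id, rows=rows,
                        notes=list(_NOTES.get(table_id, [])))


def table6_membership_matrices() -> list[MembershipMatrix]:
    """The worked example's three R_i matrices (features x classes).

    The stored table has one row per class and one column per feature;
    each R_i is the transposed 3 x 3 block of its category, so each row
    (one sub-factor) sums to one.
    """
    fix = load_fixture("table6")
    by_class = {r["class"]: r for r in fix.rows}
    matrices = []
    for ci, cat in enumerate(CATEGORIES):
        feats = FEATURE_ORDER[3 * ci:3 * ci + 3]
        entries = np.array([[float(by_class[c][f]) for c in CLASSES]
                            for f in feats])
        matrices.append(MembershipMatrix(entries=entries, category=cat,
                                         classes=CLASSES))
    return matrices


def worked_example_values() -> dict:
    """Printed and recomputed values of the worked grading example."""
    return load_fixture("worked_example").rows[0]
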