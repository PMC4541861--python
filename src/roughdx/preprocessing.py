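"""Attribute filtering, composite-column splitting and missing-value
treatment for longitudinal clinical decision tables.

The missing-value protocol is a three-tier deterministic scheme:

* dataset level — an attribute missing in >= 20% of all records is dropped;
* patient level, count rule — an attribute missing in at most two encounters
  of a patient is filled from the immediate previous/next encounter of the
  same patient (previous for the first and next for the second when the two
  missing encounters are consecutive);
* patient level, rate rule — missing in <= 20% of a patient's encounters is
  filled with the patient's own mean (numeric) or most frequent value
  (nominal); above that, the class-wide mean/mode over all patients of the
  same decision class is used.

The count rule is checked first, so a patient with 2 of 4 encounters missing
still uses previous/next.  Observed cells are never altered.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .data_model import MISSING, DecisionTable, ValidationError


class PreprocessingError(ValueError):
    pass


#: Default composite columns and their ordered parts.
DEFAULT_COMPOSITES = {
    "BP": ("SBP", "DBP"),
    "Lipids": ("TC", "TG", "HDL", "LDL"),
    "AST/ALT": ("AST", "ALT"),
}


@dataclass
class ImputationReport:
    """Audit trail of dropped attributes and every filled cell."""

    dropped_attributes: dict = field(default_factory=dict)   # name -> reason
    filled_cells: list = field(default_factory=list)         # (pid, eid, attr, strategy, value)

    def strategies_used(self) -> Counter:
        return Counter(entry[3] for entry in self.filled_cells)


def split_composites(table: DecisionTable, rules: dict | None = None) -> DecisionTable:
    """Replace composite "a/b"-style columns by their parts.

    Tables without composite columns pass through unchanged (idempotent).
    """
    from .data_model import AttributeSpec

    rules = DEFAULT_COMPOSITES if rules is None else rules
    present = [c for c in rules if any(a.name == c for a in table.attributes)]
    if not present:
        return table

    out = table.copy()
    new_attrs = []
    for a in out.attributes:
        if a.name in rules:
            for part in rules[a.name]:
                new_attrs.append(AttributeSpec(part, "continuous", a.role, a.units))
        else:
            new_attrs.append(a)
    for r in out.records:
        for comp in present:
            parts = rules[comp]
            raw = r.values.pop(comp, MISSING)
            if raw is MISSING:
                for p in parts:
                    r.values[p] = MISSING
                continue
            pieces = str(raw).split("/")
            if len(pieces) != len(parts):
                raise PreprocessingError(
                    f"cell {comp}={raw!r} for patient {r.pid} encounter "
                    f"{r.encounter_id}: expected {len(parts)} parts"
                )
            for p, piece in zip(parts, pieces):
                piece = piece.strip()
                r.values[p] = MISSING if piece == "" else float(piece)
    out.attributes = new_attrs
    return out


def drop_high_missing(table: DecisionTable, threshold: float = 0.20):
    """Drop condition attributes whose dataset-scope missing fraction is
    >= threshold.  Decision and identifier attributes are never dropped."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    from .data_model import missingness_profile

    report = ImputationReport()
    profile = missingness_profile(table)
    doomed = {
        a.name
        for a in table.attributes
        if a.role == "condition" and profile.get(a.name, 0.0) >= threshold
    }
    keep = [a for a in table.attributes if a.name not in doomed]
    if not any(a.role == "condition" for a in keep):
        raise PreprocessingError("dropping would leave zero condition attributes")
    for name in sorted(doomed):
        report.dropped_attributes[name] = (
            f"missing in {profile[name]:.1%} of records (threshold {threshold:.0%})"
        )
    out = table.copy()
    out.attributes = keep
    for r in out.records:
        for name in doomed:
            r.values.pop(name, None)
    return out, report


def _nearest_observed(seq, pos, direction):
    """Nearest non-missing value before (-1) or after (+1) position pos."""
    i = pos + direction
    while 0 <= i < len(seq):
        if seq[i] is not MISSING:
            return seq[i]
        i += direction
    return MISSING


def _patient_fill(seq, missing_pos):
    """Previous/next filling for <= 2 missing encounters of one patient.

    Returns (position, strategy, value) triples; MISSING value signals that
    no neighbour exists and the caller must fall back.
    """
    fills = []
    consecutive = (
        len(missing_pos) == 2 and missing_pos[1] == missing_pos[0] + 1
    )
    for j, pos in enumerate(missing_pos):
        if consecutive and j == 0:
            v = _nearest_observed(seq, pos, -1)
            strategy = "prev"
            if v is MISSING:
                v, strategy = _nearest_observed(seq, pos, +1), "next"
        elif consecutive and j == 1:
            v = _nearest_observed(seq, pos, +1)
            strategy = "next"
            if v is MISSING:
                v, strategy = _nearest_observed(seq, pos, -1), "prev"
        else:
            v = _nearest_observed(seq, pos, -1)
            strategy = "prev"
            if v is MISSING:
                v, strategy = _nearest_observed(seq, pos, +1), "next"
        fills.append((pos, strategy, v))
    return fills


def _mode_earliest(values):
    """Most frequent value; ties broken by earliest occurrence."""
    counts = Counter(values)
    best = max(counts.values())
    for v in values:
        if counts[v] == best:
            return v
    raise ValueError("empty sequence")


def impute(table: DecisionTable):
    """Fill every MISSING cell of the retained condition attributes.

    Returns the completed table and an :class:`ImputationReport`.  Raises if
    an attribute is missing for an entire decision class (no fallback left).
    """
    d_attr = table.decision_attribute
    if any(r.values.get(d_attr, MISSING) is MISSING for r in table.records):
        raise ValidationError("decision labels must be present before imputation")

    out = table.copy()
    report = ImputationReport()
    patients = out.patients()
    cond_attrs = [a for a in out.attributes if a.role == "condition"]

    # class-level statistics from *observed* cells only
    class_pool: dict = {}
    for r in out.records:
        cls = r.values[d_attr]
        for a in cond_attrs:
            v = r.values.get(a.name, MISSING)
            if v is not MISSING:
                class_pool.setdefault((cls, a.name), []).append(v)

    def class_fill(cls, attr):
        pool = class_pool.get((cls, attr.name))
        if not pool:
            raise PreprocessingError(
                f"attribute {attr.name} entirely missing for class {cls}"
            )
        if attr.kind == "continuous":
            return sum(pool) / len(pool), "class_average"
        return _mode_earliest(pool), "class_frequent"

    for pid, idx in patients.items():
        recs = [out.records[i] for i in idx]
        cls = recs[0].values[d_attr]
        for attr in cond_attrs:
            seq = [r.values.get(attr.name, MISSING) for r in recs]
            missing_pos = [i for i, v in enumerate(seq) if v is MISSING]
            if not missing_pos:
                continue
            observed = [v for v in seq if v is not MISSING]
            fills = []
            if len(missing_pos) <= 2 and observed:
                fills = _patient_fill(seq, missing_pos)
            elif observed and len(missing_pos) / len(seq) <= 0.20:
                if attr.kind == "continuous":
                    value, strategy = sum(observed) / len(observed), "patient_average"
                else:
                    value, strategy = _mode_earliest(observed), "patient_frequent"
                fills = [(pos, strategy, value) for pos in missing_pos]
            if not fills or any(v is MISSING for _, _, v in fills):
                value, strategy = class_fill(cls, attr)
                fills = [(pos, strategy, value) for pos in missing_pos]
            for pos, strategy, value in fills:
                recs[pos].values[attr.name] = value
                report.filled_cells.append(
                    (pid, recs[pos].encounter_id, attr.name, strategy, value)
                )
    return out, report


def preprocess(table: DecisionTable, threshold: float = 0.20,
               composites: dict | None = None):
    """Full preprocessing pipeline: split composites, drop high-missing
    attributes, impute the rest.  Returns (table, merged report)."""
    t = split_composites(table, composites)
    t, drop_report = drop_high_missing(t, threshold)
    t, fill_report = impute(t)
    fill_report.dropped_attributes.update(drop_report.dropped_attributes)
    return t, fill_report
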