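"""Core domain types for tabular clinical decision tables.

A decision table (the rough-set "information system") is a sequence of
per-encounter records described by condition attributes plus exactly one
decision attribute.  Patients are identified by ``PID`` and encounters by a
1-based chronological ``EncounterID``.  Missing cells are represented by a
dedicated :data:`MISSING` sentinel so that nominal attributes can be missing
too and so that ``0`` is never confused with absence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence


class _Missing:
    """Singleton sentinel for an absent cell value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

#: Canonical condition/decision attribute names after preprocessing.
CANONICAL_ATTRIBUTES = [
    "Gender", "Age", "BMI", "SBP", "DBP", "FBS", "Hba1c",
    "TC", "TG", "HDL", "LDL", "AST", "ALT", "TDM",
]

#: Alias map absorbing naming variants between sources (liver enzymes in
#: particular appear as SGPT/SGOT or PT/OT in different listings).
DEFAULT_ALIASES = {
    "SGPT": "ALT",
    "SGOT": "AST",
    "PT": "ALT",
    "OT": "AST",
    "HBA1C": "Hba1c",
    "HbA1c": "Hba1c",
}

DEFAULT_SENTINELS = ("", "NA", "N/A", "?", "NaN", "nan")


def canonical_name(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Map an attribute name through the alias table."""
    table = DEFAULT_ALIASES if aliases is None else {**DEFAULT_ALIASES, **aliases}
    return table.get(name, name)


@dataclass(frozen=True)
class AttributeSpec:
    """Declaration of one column of a decision table."""

    name: str
    kind: str = "continuous"          # continuous | nominal
    role: str = "condition"           # condition | decision | identifier
    units: str = ""

    def __post_init__(self):
        if self.kind not in ("continuous", "nominal"):
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.role not in ("condition", "decision", "identifier"):
            raise ValueError(f"unknown attribute role {self.role!r}")


@dataclass
class EncounterRecord:
    """One clinical encounter: a patient id, a 1-based encounter ordinal and
    a mapping of attribute name to value (numeric, nominal or MISSING)."""

    pid: str
    encounter_id: int
    values: dict

    def get(self, name: str):
        return self.values.get(name, MISSING)


class SchemaError(ValueError):
    pass


class ParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


@dataclass
class DecisionTable:
    """A rough-set information system over encounter records.

    ``discrete=True`` flags a table whose continuous condition attributes
    have been replaced by interval codes; ``interval_maps`` then carries the
    code -> printed-interval sidecar used when rendering rules.
    """

    attributes: list[AttributeSpec]
    records: list[EncounterRecord]
    discrete: bool = False
    interval_maps: dict = field(default_factory=dict)

    def __post_init__(self):
        decisions = [a for a in self.attributes if a.role == "decision"]
        if len(decisions) != 1:
            raise SchemaError(
                f"decision table needs exactly one decision attribute, got {len(decisions)}"
            )

    # -- schema helpers -------------------------------------------------
    @property
    def decision_attribute(self) -> str:
        return next(a.name for a in self.attributes if a.role == "decision")

    @property
    def condition_attributes(self) -> list[str]:
        return [a.name for a in self.attributes if a.role == "condition"]

    @property
    def identifier_attributes(self) -> list[str]:
        return [a.name for a in self.attributes if a.role == "identifier"]

    def spec(self, name: str) -> AttributeSpec:
        for a in self.attributes:
            if a.name == name:
                return a
        raise SchemaError(f"unknown attribute {name!r}")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def decision_domain(self) -> set:
        d = self.decision_attribute
        return {r.values[d] for r in self.records if r.values.get(d) is not MISSING}

    # -- data access ----------------------------------------------------
    def column(self, name: str) -> list:
        self.spec(name)
        return [r.values.get(name, MISSING) for r in self.records]

    def decisions(self) -> list:
        return self.column(self.decision_attribute)

    def subset(self, indices: Iterable[int]) -> "DecisionTable":
        idx = list(indices)
        return DecisionTable(
            attributes=list(self.attributes),
            records=[self.records[i] for i in idx],
            discrete=self.discrete,
            interval_maps=dict(self.interval_maps),
        )

    def copy(self) -> "DecisionTable":
        return DecisionTable(
            attributes=list(self.attributes),
            records=[replace(r, values=dict(r.values)) for r in self.records],
            discrete=self.discrete,
            interval_maps=dict(self.interval_maps),
        )

    def patients(self) -> dict:
        """Records grouped per patient, in encounter order."""
        groups: dict = {}
        for i, r in enumerate(self.records):
            groups.setdefault(r.pid, []).append(i)
        for pid in groups:
            groups[pid].sort(key=lambda i: self.records[i].encounter_id)
        return groups


def class_counts(table: DecisionTable) -> dict:
    """Per-decision-class record counts; errors on MISSING decisions."""
    d = table.decision_attribute
    offenders = [
        (r.pid, r.encounter_id)
        for r in table.records
        if r.values.get(d, MISSING) is MISSING
    ]
    if offenders:
        raise ValidationError(f"records with MISSING decision: {offenders[:10]}")
    counts: dict = {}
    for r in table.records:
        counts[r.values[d]] = counts.get(r.values[d], 0) + 1
    return counts


def missingness_profile(table: DecisionTable, scope: str = "dataset",
                        pid: str | None = None) -> dict:
    """Fraction of MISSING cells per attribute.

    scope="dataset" computes over all records; scope="patient" restricts to
    one patient's encounters.
    """
    if scope == "patient":
        if pid is None:
            raise ValueError("patient scope requires pid")
        recs = [r for r in table.records if r.pid == pid]
    else:
        recs = table.records
    n = len(recs)
    out = {}
    for a in table.attributes:
        if a.role == "identifier":
            continue
        miss = sum(1 for r in recs if r.values.get(a.name, MISSING) is MISSING)
        out[a.name] = miss / n if n else 0.0
    return out


def _parse_cell(text: str, sentinels: Sequence[str]):
    if text in sentinels:
        return MISSING
    try:
        v = float(text)
        return int(v) if v.is_integer() and "." not in text and "e" not in text.lower() else v
    except ValueError:
        return text


def read_table(path, dialect: str = "csv",
               schema: Sequence[AttributeSpec] | None = None,
               decision: str = "TDM",
               sentinels: Sequence[str] = DEFAULT_SENTINELS,
               aliases: Mapping[str, str] | None = None) -> DecisionTable:
    """Read a decision table from a delimited text file.

    The header row names attributes; ``PID``/``EncounterID`` columns become
    identifiers, the ``decision`` column the decision attribute, everything
    else a condition attribute.  Blank cells and the configured sentinels
    become MISSING.
    """
    delim = {"csv": ",", "tsv": "\t"}[dialect]
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file")
        header = [canonical_name(h.strip(), aliases) for h in header]
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rows.append(row)

    if schema is not None:
        specs = {canonical_name(s.name, aliases): s for s in schema}
        decision_cols = [n for n, s in specs.items() if s.role == "decision"]
        if decision_cols:
            decision = decision_cols[0]
    else:
        specs = {}
    if decision not in header:
        raise SchemaError(f"decision column {decision!r} not found in header {header}")

    # classify columns; numeric if every non-missing cell parses as a number
    parsed = [[_parse_cell(c.strip(), sentinels) for c in row] for row in rows]
    attributes = []
    for j, name in enumerate(header):
        if name in specs:
            attributes.append(specs[name])
            continue
        if name in ("PID", "EncounterID"):
            attributes.append(AttributeSpec(name, "nominal", "identifier"))
        elif name == decision:
            attributes.append(AttributeSpec(name, "nominal", "decision"))
        else:
            col = [row[j] for row in parsed if row[j] is not MISSING]
            numeric = bool(col) and all(isinstance(v, (int, float)) for v in col)
            attributes.append(AttributeSpec(name, "continuous" if numeric else "nominal"))

    records = []
    counters: dict = {}
    for row in parsed:
        values = dict(zip(header, row))
        pid = str(values.pop("PID", f"P{len(records) + 1:03d}"))
        eid = values.pop("EncounterID", None)
        if eid is None or eid is MISSING:
            counters[pid] = counters.get(pid, 0) + 1
            eid = counters[pid]
        records.append(EncounterRecord(pid=pid, encounter_id=int(eid), values=values))
    attributes = [a for a in attributes if a.name not in ("PID", "EncounterID")]
    attributes = [AttributeSpec("PID", "nominal", "identifier"),
                  AttributeSpec("EncounterID", "nominal", "identifier")] + attributes
    return DecisionTable(attributes=attributes, records=records)


def write_table(table: DecisionTable, path, dialect: str = "csv") -> None:
    """Write a decision table; MISSING cells become blank. Round-trips with
    :func:`read_table`."""
    delim = {"csv": ",", "tsv": "\t"}[dialect]
    data_cols = [a.name for a in table.attributes if a.role != "identifier"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["PID", "EncounterID"] + data_cols)
        for r in table.records:
            row = [r.pid, r.encounter_id]
            for name in data_cols:
                v = r.values.get(name, MISSING)
                row.append("" if v is MISSING else v)
            writer.writerow(row)
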