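"""Shared test utilities: tiny table builders and independent brute-force
oracles for reduct search and minimal rule covering."""

from __future__ import annotations

from itertools import combinations

from roughdx.data_model import AttributeSpec, DecisionTable, EncounterRecord
from roughdx.roughset import quality_of_classification


def make_table(rows, decision="d", discrete=True, kinds=None):
    """Build a DecisionTable from a list of per-record dicts (one key is the
    decision)."""
    names = [k for k in rows[0] if k != decision]
    kinds = kinds or {}
    attrs = [AttributeSpec(n, kinds.get(n, "nominal"), "condition") for n in names]
    attrs.append(AttributeSpec(decision, "nominal", "decision"))
    records = [
        EncounterRecord(pid=f"P{i + 1:03d}", encounter_id=1, values=dict(r))
        for i, r in enumerate(rows)
    ]
    return DecisionTable(attributes=attrs, records=records, discrete=discrete)


def random_table(rng, n_attrs, n_records, n_values=3, n_classes=2):
    """Random discrete decision table for oracle-equivalence testing."""
    rows = []
    for _ in range(n_records):
        row = {f"a{j}": int(rng.integers(n_values)) for j in range(n_attrs)}
        row["d"] = f"c{int(rng.integers(n_classes))}"
        rows.append(row)
    return make_table(rows)


def exhaustive_reducts(table):
    """All minimal attribute subsets preserving full quality, by checking
    every subset of the power set (independent of the lattice search)."""
    attrs = table.condition_attributes
    full = quality_of_classification(table, attrs)
    qualifying = []
    for k in range(1, len(attrs) + 1):
        for sub in combinations(attrs, k):
            if abs(quality_of_classification(table, sub) - full) < 1e-12:
                qualifying.append(frozenset(sub))
    return {
        s for s in qualifying
        if not any(o < s for o in qualifying if o != s)
    }


def _consistent_blocks(table, target, attrs):
    """Coverage sets of every conjunctive condition set lying inside the
    target, deduplicated and reduced to maximal coverages."""
    target = frozenset(target)
    extents = {}
    for i, r in enumerate(table.records):
        for a in attrs:
            extents.setdefault((a, r.values[a]), set()).add(i)
    blocks = set()
    for k in range(1, len(attrs) + 1):
        for sub in combinations(attrs, k):
            seen = set()
            for i in target:
                key = tuple(table.records[i].values[a] for a in sub)
                if key in seen:
                    continue
                seen.add(key)
                block = frozenset(
                    set.intersection(*(extents[(a, v)] for a, v in zip(sub, key)))
                )
                if block <= target:
                    blocks.add(block)
    # dominated coverages can never shrink a minimum cover
    return [b for b in blocks if not any(b < o for o in blocks)]


def brute_force_min_cover_size(table, target, attrs=None):
    """Minimum number of consistent condition sets covering the target."""
    attrs = attrs or table.condition_attributes
    target = frozenset(target)
    if not target:
        return 0
    blocks = _consistent_blocks(table, target, attrs)
    for r in range(1, len(blocks) + 1):
        for combo in combinations(blocks, r):
            if frozenset().union(*combo) >= target:
                return r
    raise AssertionError("target not coverable by consistent condition sets")
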