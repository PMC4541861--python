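"""LEM2 minimal-covering rule induction and rule statistics.

Certain rules are induced from the lower approximation of each decision
class; if the table is inconsistent, approximate rules are induced from the
boundary region and carry every class observed there.  Each rule records
its support (training records matching the conditions and a covered class),
per-class strength used for classification voting, and significance
(percentage of its own class covered).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .data_model import DecisionTable
from .roughset import (approximate, concepts, find_all_reducts,
                       indiscernibility_classes)


class InductionError(ValueError):
    pass


@dataclass(frozen=True)
class Condition:
    attribute: str
    value: object   # interval code (int) or nominal value

    def matches(self, values: dict) -> bool:
        return values.get(self.attribute) == self.value


@dataclass
class DecisionRule:
    conditions: tuple
    decisions: tuple          # one class (certain) or >=2 (approximate)
    kind: str                 # certain | approximate
    support: int              # records matching conditions and a covered class
    class_support: dict       # class -> matching records of that class
    significance: float | None = None   # certain rules only, percent

    @property
    def strength(self):
        """Voting weight: support for certain rules, per-class support for
        approximate rules."""
        if self.kind == "certain":
            return self.support
        return dict(self.class_support)

    def matches(self, values: dict) -> bool:
        return all(c.matches(values) for c in self.conditions)

    def similarity(self, values: dict) -> float:
        if not self.conditions:
            return 0.0
        hit = sum(1 for c in self.conditions if c.matches(values))
        return hit / len(self.conditions)

    def render(self, interval_maps: dict | None = None,
               class_sizes: dict | None = None) -> str:
        maps = interval_maps or {}
        parts = []
        for c in self.conditions:
            shown = maps.get(c.attribute, {}).get(c.value, c.value)
            parts.append(f"({c.attribute} = {shown})")
        head = " OR ".join(f"({d})" for d in self.decisions)
        body = " and ".join(parts)
        if self.kind == "certain":
            stat = f"{self.support} ({self.significance:.2f}%)"
        else:
            sizes = class_sizes or {}
            stat = " ".join(
                f"[{self.class_support.get(d, 0)}, {sizes.get(d, self.class_support.get(d, 0))}]"
                for d in self.decisions)
        return f"{head} {body}  {stat}"


@dataclass
class RuleSet:
    rules: list
    training_class_sizes: dict
    scheme_snapshot: dict = field(default_factory=dict)
    attributes_used: tuple = ()

    @property
    def certain(self):
        return [r for r in self.rules if r.kind == "certain"]

    @property
    def approximate(self):
        return [r for r in self.rules if r.kind == "approximate"]

    def to_json(self, path=None) -> str:
        payload = {
            "training_class_sizes": self.training_class_sizes,
            "attributes_used": list(self.attributes_used),
            "scheme_snapshot": {a: {str(k): v for k, v in m.items()}
                                for a, m in self.scheme_snapshot.items()},
            "rules": [
                {
                    "conditions": [[c.attribute, c.value] for c in r.conditions],
                    "decisions": list(r.decisions),
                    "kind": r.kind,
                    "support": r.support,
                    "class_support": r.class_support,
                    "significance": r.significance,
                    "rendered": r.render(self.scheme_snapshot, self.training_class_sizes),
                }
                for r in self.rules
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "RuleSet":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        rules = [
            DecisionRule(
                conditions=tuple(Condition(a, v) for a, v in r["conditions"]),
                decisions=tuple(r["decisions"]),
                kind=r["kind"],
                support=r["support"],
                class_support=r["class_support"],
                significance=r["significance"],
            )
            for r in payload["rules"]
        ]
        snapshot = {a: {int(k) if k.lstrip("-").isdigit() else k: v
                        for k, v in m.items()}
                    for a, m in payload.get("scheme_snapshot", {}).items()}
        return cls(rules=rules,
                   training_class_sizes=payload["training_class_sizes"],
                   scheme_snapshot=snapshot,
                   attributes_used=tuple(payload.get("attributes_used", ())))


def rule_significance(support: int, concept_size: int) -> float:
    """100 * support / concept_size, half-up rounded to 2 decimals."""
    if concept_size < 1:
        raise InductionError("concept size must be >= 1")
    if not (0 <= support <= concept_size):
        raise InductionError("support must lie in [0, concept_size]")
    pct = Decimal(100 * support) / Decimal(concept_size)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _pair_extent(table, attrs):
    """(attribute, value) -> set of record indices, for condition attrs."""
    extent: dict = {}
    for i, r in enumerate(table.records):
        for a in attrs:
            extent.setdefault((a, r.values[a]), set()).add(i)
    return extent


def lem2_cover(table: DecisionTable, target, attrs=None) -> list:
    """LEM2 local covering of a target region by condition sets.

    The target must be a union of indiscernibility blocks over ``attrs``
    (i.e. a lower or boundary approximation).  Greedy pair selection
    maximises overlap with the yet-uncovered part of the target; ties break
    on smaller pair extent, then canonical attribute order, then ascending
    value.  Redundant pairs and redundant condition sets are pruned, so each
    returned set is minimal and the union covers the target exactly.
    """
    attrs = list(attrs) if attrs is not None else table.condition_attributes
    target = set(target)
    if not target:
        return []
    for block in indiscernibility_classes(table, attrs):
        inter = block & target
        if inter and inter != block:
            raise InductionError(
                "target is not a union of indiscernibility blocks; pass an "
                "approximation, not an arbitrary record set")

    extent = _pair_extent(table, attrs)
    attr_order = {a: i for i, a in enumerate(attrs)}
    coverings = []
    covered_sets = []
    G = set(target)
    while G:
        T: list = []
        block = None   # records matched by all pairs in T
        G_local = set(G)
        while block is None or not block <= target:
            best, best_key = None, None
            for (a, v), ext in extent.items():
                if (a, v) in T:
                    continue
                overlap = len(ext & G_local)
                if overlap == 0:
                    continue
                key = (-overlap, len(ext), attr_order[a], str(v))
                if best_key is None or key < best_key:
                    best, best_key = (a, v), key
            if best is None:
                raise InductionError("LEM2 failed to extend a condition set")
            T.append(best)
            block = (block & extent[best]) if block is not None else set(extent[best])
            G_local &= extent[best]
        # prune redundant pairs
        for t in list(T):
            if len(T) == 1:
                break
            trial = [p for p in T if p != t]
            trial_block = set.intersection(*(extent[p] for p in trial))
            if trial_block <= target:
                T = trial
                block = trial_block
        coverings.append(T)
        covered_sets.append(block)
        G -= block
    # drop condition sets whose coverage is subsumed by the union of the rest
    keep = list(range(len(coverings)))
    for i in range(len(coverings)):
        others = set().union(*(covered_sets[j] for j in keep if j != i)) if len(keep) > 1 else set()
        if i in keep and covered_sets[i] <= others:
            keep.remove(i)
    return [tuple(coverings[i]) for i in keep]


def induce_rules(table: DecisionTable, attrs: str | list = "core") -> RuleSet:
    """Induce a LEM2 rule set from a discrete, complete decision table.

    ``attrs`` selects the condition attributes: "core" (default) runs the
    reduct search and keeps the core, "all" uses every condition attribute,
    or pass an explicit list.
    """
    if not table.discrete:
        raise InductionError("rule induction requires a discrete table")
    if table.n_records == 0:
        raise InductionError("empty training table")

    if attrs == "all":
        use = table.condition_attributes
    elif attrs == "core":
        core = find_all_reducts(table).core
        if core:
            use = [a for a in table.condition_attributes if a in core]
        else:
            warnings.warn("core is empty; inducing on all condition attributes")
            use = table.condition_attributes
    else:
        use = list(attrs)

    extent = _pair_extent(table, use)

    def matched(conds):
        return set.intersection(*(extent[p] for p in conds))

    class_sizes = {c.label: len(c.members) for c in concepts(table)}
    rules = []
    boundary = set()
    for concept in concepts(table):
        approx = approximate(table, use, concept)
        boundary |= approx.boundary
        for conds in lem2_cover(table, approx.lower, use):
            m = matched(conds)
            support = len(m)
            rules.append(DecisionRule(
                conditions=tuple(Condition(a, v) for a, v in conds),
                decisions=(concept.label,),
                kind="certain",
                support=support,
                class_support={concept.label: support},
                significance=rule_significance(support, class_sizes[concept.label]),
            ))
    if boundary:
        decisions_col = table.decisions()
        for conds in lem2_cover(table, boundary, use):
            m = matched(conds)
            per_class: dict = {}
            for i in m:
                per_class[decisions_col[i]] = per_class.get(decisions_col[i], 0) + 1
            labels = tuple(sorted(per_class, key=str))
            rules.append(DecisionRule(
                conditions=tuple(Condition(a, v) for a, v in conds),
                decisions=labels,
                kind="approximate",
                support=len(m),
                class_support=per_class,
            ))
    return RuleSet(rules=rules, training_class_sizes=class_sizes,
                   scheme_snapshot=dict(table.interval_maps),
                   attributes_used=tuple(use))
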