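"""Rough set fundamentals over discrete decision tables.

Implements indiscernibility partitions, lower/upper approximations, the
positive region and the quality-of-classification measure (gamma), an
exhaustive bottom-up lattice search for all decision-relative reducts, and
the core as the intersection of all reducts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data_model import DecisionTable


class RoughSetError(ValueError):
    pass


@dataclass(frozen=True)
class Concept:
    """A decision class viewed as a set of record indices."""

    label: object
    members: frozenset


@dataclass(frozen=True)
class ApproximationResult:
    lower: frozenset
    upper: frozenset

    @property
    def boundary(self) -> frozenset:
        return self.upper - self.lower


@dataclass
class ReductSet:
    reducts: list            # list of frozenset of attribute names
    core: frozenset
    frequencies: dict        # attribute -> fraction of reducts containing it
    full_quality: float


def concepts(table: DecisionTable) -> list:
    """Decision classes as concepts, in sorted label order."""
    decisions = table.decisions()
    labels = sorted(set(decisions), key=str)
    return [
        Concept(lab, frozenset(i for i, d in enumerate(decisions) if d == lab))
        for lab in labels
    ]


def _check_attrs(table: DecisionTable, attrs) -> list:
    attrs = list(attrs)
    if not attrs:
        raise RoughSetError("attribute set must be non-empty")
    known = set(table.condition_attributes)
    unknown = [a for a in attrs if a not in known]
    if unknown:
        raise RoughSetError(f"unknown condition attributes: {unknown}")
    return attrs


def indiscernibility_classes(table: DecisionTable, attrs) -> list:
    """Partition of record indices: two records share a block iff they agree
    on every attribute in attrs."""
    attrs = _check_attrs(table, attrs)
    blocks: dict = {}
    for i, r in enumerate(table.records):
        key = tuple(r.values[a] for a in attrs)
        blocks.setdefault(key, []).append(i)
    return [frozenset(b) for b in blocks.values()]


def approximate(table: DecisionTable, attrs, concept: Concept) -> ApproximationResult:
    """Lower/upper approximation of a concept under the attrs-partition."""
    lower, upper = set(), set()
    for block in indiscernibility_classes(table, attrs):
        inter = block & concept.members
        if inter:
            upper |= block
            if block <= concept.members:
                lower |= block
    return ApproximationResult(frozenset(lower), frozenset(upper))


class _FastTable:
    """Integer-coded columns for vectorised positive-region computation."""

    def __init__(self, table: DecisionTable):
        self.attrs = table.condition_attributes
        self.n = table.n_records
        self.cols = {}
        self.radix = {}
        for a in self.attrs:
            col = table.column(a)
            _, inv = np.unique(np.asarray(col, dtype=object), return_inverse=True)
            self.cols[a] = inv.astype(np.int64)
            self.radix[a] = int(inv.max()) + 1 if self.n else 1
        _, self.dec = np.unique(
            np.asarray(table.decisions(), dtype=object), return_inverse=True)
        self.n_classes = int(self.dec.max()) + 1 if self.n else 0

    def positive_region_size(self, attrs) -> int:
        key = np.zeros(self.n, dtype=np.int64)
        for a in attrs:
            key = key * self.radix[a] + self.cols[a]
        _, inv = np.unique(key, return_inverse=True)
        n_blocks = int(inv.max()) + 1
        # count (block, class) occupancy; a block is positive iff pure
        occupancy = np.zeros((n_blocks, self.n_classes), dtype=np.int64)
        np.add.at(occupancy, (inv, self.dec), 1)
        pure = (occupancy > 0).sum(axis=1) == 1
        sizes = occupancy.sum(axis=1)
        return int(sizes[pure].sum())


def quality_of_classification(table: DecisionTable, attrs) -> float:
    """gamma(attrs): fraction of records inside some lower approximation."""
    attrs = _check_attrs(table, attrs)
    if table.n_records == 0:
        raise RoughSetError("empty table")
    ft = _FastTable(table)
    return ft.positive_region_size(attrs) / table.n_records


def find_all_reducts(table: DecisionTable, max_attributes: int = 20) -> ReductSet:
    """All decision-relative reducts by exhaustive bottom-up lattice search.

    A subset qualifies iff its quality equals the full-attribute quality;
    supersets of qualifying subsets are pruned, so the returned sets are
    exactly the minimal ones (gamma is monotone in the attribute set).
    """
    if not table.discrete:
        raise RoughSetError("reduct search requires a discrete table")
    attrs = table.condition_attributes
    if len(attrs) > max_attributes:
        raise RoughSetError(
            f"{len(attrs)} condition attributes exceed the exhaustive-search "
            f"cap ({max_attributes}); heuristic search is out of scope"
        )
    ft = _FastTable(table)
    n = table.n_records
    full_pos = ft.positive_region_size(attrs)
    reducts = []
    for k in range(1, len(attrs) + 1):
        for subset in combinations(attrs, k):
            sset = frozenset(subset)
            if any(red <= sset for red in reducts):
                continue
            if ft.positive_region_size(subset) == full_pos:
                reducts.append(sset)
    core = core_from_reducts(reducts)
    freqs = {a: sum(a in r for r in reducts) / len(reducts) for a in attrs}
    return ReductSet(reducts=reducts, core=core, frequencies=freqs,
                     full_quality=full_pos / n if n else 1.0)


def reduct_frequencies(reducts, attributes=None) -> dict:
    """Fraction of reducts containing each attribute; ``attributes`` extends
    the tally to attributes appearing in no reduct (frequency 0)."""
    reducts = [frozenset(r) for r in reducts]
    if not reducts:
        raise RoughSetError("need at least one reduct")
    names = set().union(*reducts) | set(attributes or ())
    return {a: sum(a in r for r in reducts) / len(reducts) for a in sorted(names)}


def core_from_reducts(reducts) -> frozenset:
    """Core = exact intersection of all reducts."""
    reducts = [frozenset(r) for r in reducts]
    if not reducts:
        raise RoughSetError("need at least one reduct")
    core = set(reducts[0])
    for r in reducts[1:]:
        core &= r
    return frozenset(core)
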