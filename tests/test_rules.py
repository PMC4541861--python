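"""LEM2 covering, induced rule sets and rule statistics, checked against a
brute-force minimal-covering oracle on small random tables."""

import numpy as np
import pytest

from roughdx.roughset import approximate, concepts
from roughdx.rules import (InductionError, RuleSet, induce_rules, lem2_cover,
                           rule_significance)

from _helpers import brute_force_min_cover_size, make_table, random_table


class TestRuleSignificance:
    @pytest.mark.parametrize("support,size,expected", [
        (20, 113, 17.70),
        (17, 278, 6.12),
        (23, 278, 8.27),
        (7, 113, 6.19),
        (0, 100, 0.00),
        (113, 113, 100.00),
    ])
    def test_half_up_two_decimals(self, support, size, expected):
        assert rule_significance(support, size) == expected

    def test_errors(self):
        with pytest.raises(InductionError):
            rule_significance(1, 0)
        with pytest.raises(InductionError):
            rule_significance(5, 4)


class TestLem2Cover:
    def test_single_pair_target(self):
        # block a=1 is pure; other attributes are noise
        rows = [{"a": 1, "b": i % 2, "d": "X"} for i in range(4)]
        rows += [{"a": 0, "b": i % 2, "d": "Y"} for i in range(4)]
        t = make_table(rows)
        cover = lem2_cover(t, {0, 1, 2, 3})
        assert cover == [(("a", 1),)]

    def test_empty_target(self):
        t = make_table([{"a": 0, "d": "X"}])
        assert lem2_cover(t, set()) == []

    def test_non_block_target_rejected(self):
        t = make_table([{"a": 0, "d": "X"}, {"a": 0, "d": "Y"}])
        with pytest.raises(InductionError):
            lem2_cover(t, {0})

    def test_known_minimal_covering(self):
        rows = [
            {"a": 0, "b": 0, "c": 0, "d": "X"},
            {"a": 0, "b": 1, "c": 0, "d": "X"},
            {"a": 1, "b": 0, "c": 1, "d": "X"},
            {"a": 1, "b": 1, "c": 1, "d": "Y"},
            {"a": 2, "b": 0, "c": 1, "d": "Y"},
            {"a": 2, "b": 1, "c": 0, "d": "Y"},
        ]
        t = make_table(rows)
        target = {0, 1, 2}
        cover = lem2_cover(t, target)
        assert len(cover) == brute_force_min_cover_size(t, target)
        covered = set()
        for conds in cover:
            block = set(range(len(rows)))
            for a, v in conds:
                block &= {i for i, r in enumerate(rows) if r[a] == v}
            assert block <= target
            covered |= block
        assert covered == target

    def test_covering_never_beats_brute_force_and_is_irredundant(self):
        # greedy local covering can exceed the global minimum cover (rarely,
        # at this scale), but it can never beat it, and no returned rule or
        # condition may be redundant
        rng = np.random.default_rng(23)
        for _ in range(30):
            t = random_table(rng, n_attrs=int(rng.integers(2, 5)),
                             n_records=int(rng.integers(4, 13)))
            concept = concepts(t)[0]
            lower = approximate(t, t.condition_attributes, concept).lower
            if not lower:
                continue
            cover = lem2_cover(t, lower)
            assert len(cover) >= brute_force_min_cover_size(t, lower)
            extents = {}
            for i, r in enumerate(t.records):
                for a in t.condition_attributes:
                    extents.setdefault((a, r.values[a]), set()).add(i)
            blocks = [set.intersection(*(extents[p] for p in conds))
                      for conds in cover]
            for k, (conds, block) in enumerate(zip(cover, blocks)):
                others = set().union(*(b for j, b in enumerate(blocks) if j != k)) \
                    if len(blocks) > 1 else set()
                assert not block <= others          # rule not redundant
                for p in conds:                      # condition not droppable
                    rest = [q for q in conds if q != p]
                    if rest:
                        assert not set.intersection(
                            *(extents[q] for q in rest)) <= lower


def _check_invariants(t, rs):
    decisions = t.decisions()
    for rule in rs.certain:
        matched = [i for i, r in enumerate(t.records) if rule.matches(r.values)]
        # consistency: never matches a foreign-class training record
        assert all(decisions[i] == rule.decisions[0] for i in matched)
        assert rule.support == len(matched) >= 1
        # condition minimality: dropping any condition breaks consistency
        for k in range(len(rule.conditions)):
            rest = rule.conditions[:k] + rule.conditions[k + 1:]
            if not rest:
                sub = list(range(len(t.records)))
            else:
                sub = [i for i, r in enumerate(t.records)
                       if all(c.matches(r.values) for c in rest)]
            assert not all(decisions[i] == rule.decisions[0] for i in sub)
    # coverage: every lower-approximation record matches a rule of its class
    for concept in concepts(t):
        lower = approximate(t, list(rs.attributes_used), concept).lower
        for i in lower:
            assert any(r.matches(t.records[i].values) for r in rs.certain
                       if r.decisions[0] == concept.label)


class TestInduceRules:
    def test_consistent_table_all_certain(self):
        rows = [{"a": 0, "b": 0, "d": "X"}, {"a": 0, "b": 1, "d": "X"},
                {"a": 1, "b": 0, "d": "Y"}, {"a": 1, "b": 1, "d": "Y"}]
        t = make_table(rows)
        rs = induce_rules(t, attrs="all")
        assert rs.approximate == []
        _check_invariants(t, rs)

    def test_mixed_block_yields_one_approximate_rule(self):
        rows = [{"a": 0, "d": "X"}, {"a": 0, "d": "Y"},
                {"a": 1, "d": "X"}, {"a": 2, "d": "Y"}]
        t = make_table(rows)
        rs = induce_rules(t, attrs="all")
        assert len(rs.approximate) == 1
        approx = rs.approximate[0]
        assert set(approx.decisions) == {"X", "Y"}
        assert approx.class_support == {"X": 1, "Y": 1}

    def test_invariants_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            t = random_table(rng, n_attrs=int(rng.integers(2, 5)),
                             n_records=int(rng.integers(4, 15)))
            rs = induce_rules(t, attrs="all")
            _check_invariants(t, rs)

    def test_rule_removal_breaks_coverage(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            t = random_table(rng, n_attrs=3, n_records=12)
            rs = induce_rules(t, attrs="all")
            decisions = t.decisions()
            for dropped in rs.certain:
                label = dropped.decisions[0]
                concept = next(c for c in concepts(t) if c.label == label)
                lower = approximate(t, list(rs.attributes_used), concept).lower
                rest = [r for r in rs.certain
                        if r is not dropped and r.decisions[0] == label]
                uncovered = [i for i in lower
                             if not any(r.matches(t.records[i].values) for r in rest)]
                assert uncovered, "every rule must cover something exclusively"

    def test_empty_table_errors(self):
        from roughdx.data_model import AttributeSpec, DecisionTable
        t = DecisionTable(
            attributes=[AttributeSpec("a", "nominal"),
                        AttributeSpec("d", "nominal", "decision")],
            records=[], discrete=True)
        with pytest.raises(InductionError):
            induce_rules(t)

    def test_core_default_on_synthetic(self, fitted):
        rs = fitted.rules
        assert set(rs.attributes_used) == set(fitted.reduct_set.core)
        assert all(r.support >= 1 for r in rs.rules)
        for r in rs.certain:
            assert 0 < r.significance <= 100


class TestSerialization:
    def test_json_round_trip(self, fitted):
        text = fitted.rules.to_json()
        back = RuleSet.from_json(text)
        assert len(back.rules) == len(fitted.rules.rules)
        for a, b in zip(fitted.rules.rules, back.rules):
            assert a.conditions == b.conditions
            assert a.decisions == b.decisions
            assert a.support == b.support

    def test_render_interval_notation(self, fitted):
        rendered = fitted.rules.rules[0].render(
            fitted.rules.scheme_snapshot, fitted.rules.training_class_sizes)
        assert "=" in rendered and "(" in rendered
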