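"""Online hybrid reasoning: rough-set prediction for new patients plus
reference-range interpretation of each observation.

For an unregistered patient the engine first runs rough-set reasoning (RSR)
over the mined prediction rules — either faithful first-match scanning in
significance order, or LERS-style voting — and then reference-range
reasoning (3R), which interprets every covered raw observation against the
guideline interval vocabulary (normal / borderline / abnormal / risky
categories).  A registered patient is routed to trend analysis instead of
being re-predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import UNCLASSIFIED, ClassifierParams, classify
from .data_model import MISSING, EncounterRecord
from .discretization import IntervalScheme, builtin_schemes
from .rules import RuleSet

UNDEFINED = "UNDEFINED"

#: Marker returned for registered patients: run trend analysis, not RSR.
ROUTE_TO_TREND = "ROUTE_TO_TREND_ANALYSIS"


class ReasoningError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceRangeRule:
    attribute: str
    interval: object          # SemanticInterval
    interpretation: str


def reference_ranges(schemes: dict | None = None) -> dict:
    """attribute -> ordered reference-range rules, sharing the discretization
    scheme vocabulary (same gap closure, so the two never disagree)."""
    schemes = schemes or builtin_schemes()
    return {
        name: [ReferenceRangeRule(name, iv, iv.label) for iv in scheme.intervals]
        for name, scheme in schemes.items()
    }


@dataclass
class HRBRResult:
    pid: str
    tdm: str                          # T1DM | T2DM | UNDEFINED
    interpretations: dict = field(default_factory=dict)
    fired_rules: list = field(default_factory=list)


def _record_values(encounter):
    if isinstance(encounter, EncounterRecord):
        return encounter.values, encounter.pid
    return dict(encounter), str(encounter.get("PID", "?"))


def perform_rsr(encounter, rules: RuleSet, mode: str = "first_match",
                params: ClassifierParams | None = None,
                approximate_fires: bool = False):
    """Rough-set reasoning over a *discretized* encounter.

    first_match scans rules in significance-descending order and returns the
    first fully satisfied rule's decision; a fired approximate rule yields
    UNDEFINED by default since it names more than one class.  lers mode
    delegates to the voting classifier.  Returns (label, fired rules).
    """
    values, _ = _record_values(encounter)
    for cond_attr in rules.attributes_used:
        if cond_attr not in values:
            raise ReasoningError(f"encounter lacks attribute {cond_attr!r}")
    if mode == "lers":
        label = classify(values, rules, params)
        return (UNDEFINED if label == UNCLASSIFIED else label), []
    if mode != "first_match":
        raise ReasoningError(f"unknown RSR mode {mode!r}")

    def order_key(r):
        sig = r.significance if r.significance is not None else -1.0
        return (-sig, rules.rules.index(r))

    for rule in sorted(rules.rules, key=order_key):
        if rule.matches(values):
            if rule.kind == "approximate" and not approximate_fires:
                return UNDEFINED, [rule]
            return rule.decisions[0], [rule]
    return UNDEFINED, []


def perform_3r(encounter, ranges: dict | None = None) -> dict:
    """Reference-range reasoning over *raw* numeric observations.

    Returns observation -> interpretation for every observation that has a
    reference table; observations without one (Age, Gender, ...) are
    omitted.  3R shares the gap-closed tiling with discretization, so every
    finite value receives exactly one interpretation.
    """
    schemes = builtin_schemes()
    if ranges is None:
        covered = {k: v for k, v in schemes.items() if k != "Age"}
    else:
        covered = {}
        for name, rr in ranges.items():
            covered[name] = rr
    values, _ = _record_values(encounter)
    out = {}
    for name, v in values.items():
        if name not in covered or v is MISSING:
            continue
        if not isinstance(v, (int, float)):
            raise ReasoningError(f"non-numeric value {v!r} for observation {name}")
        entry = covered[name]
        if isinstance(entry, IntervalScheme):
            out[name] = entry.label_for(float(v))
        else:
            # rules built from a scheme share its gap-closed tiling
            code = schemes[name].code_for(float(v))
            for rule in entry:
                if rule.interval.code == code:
                    out[name] = rule.interpretation
                    break
    return out


def discretize_encounter(encounter, schemes: dict | None = None) -> dict:
    """Map an encounter's raw numeric observations to interval codes,
    leaving nominal values untouched."""
    schemes = schemes or builtin_schemes()
    values, _ = _record_values(encounter)
    out = {}
    for name, v in values.items():
        if name in schemes and isinstance(v, (int, float)) and v is not MISSING:
            out[name] = schemes[name].code_for(float(v))
        else:
            out[name] = v
    return out


def apply_hrbr(encounter, registered: bool, rules: RuleSet,
               ranges: dict | None = None, mode: str = "first_match",
               params: ClassifierParams | None = None,
               schemes: dict | None = None):
    """Hybrid rule-based reasoning entry point over a *raw* encounter.

    Unregistered patients get rough-set prediction (on the discretized
    observations) followed by reference-range interpretation (on the raw
    values), bundled as an :class:`HRBRResult`; registered patients get the
    trend-analysis routing marker.
    """
    if registered:
        return ROUTE_TO_TREND
    values, pid = _record_values(encounter)
    disc = discretize_encounter(values, schemes)
    tdm, fired = perform_rsr(disc, rules, mode=mode, params=params)
    interpretations = perform_3r(encounter, ranges)
    return HRBRResult(pid=pid, tdm=tdm, interpretations=interpretations,
                      fired_rules=fired)
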