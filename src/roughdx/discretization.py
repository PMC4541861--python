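"""Guideline-driven semantic discretization.

Continuous clinical attributes are mapped to ordered semantic intervals
derived from published reference ranges (WHO BMI classes, JNC 7 blood
pressure stages, ADA glucose/HbA1c categories, NCEP lipid panels, liver
enzyme reference ranges).  The same interval vocabulary drives both
discretization of the decision table and reference-range interpretation of
individual observations, so the two can never disagree.

Some printed guideline interval pairs leave real-valued gaps (e.g. BMI
"[18.5, 24.9]" followed by "[25, 30)").  Schemes are normalised by *gap
closure*: each interval extends half-open up to the next cut-point and the
first interval extends to -inf, so the intervals tile the whole real line.
Printed labels and the printed inclusivity at genuine cut-points (e.g.
HbA1c upper-inclusive at 5.9/6.4/7.4) are preserved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .data_model import MISSING, DecisionTable


class DiscretizationError(ValueError):
    pass


@dataclass(frozen=True)
class SemanticInterval:
    """One labelled interval of a discretization scheme.

    ``low``/``high`` and the inclusivity flags reflect the printed guideline
    interval; the containing :class:`IntervalScheme` owns the gap-closed
    boundaries actually used for mapping values.
    """

    low: float
    high: float
    low_inclusive: bool
    high_inclusive: bool
    code: int
    label: str

    def __str__(self) -> str:
        lo = "(-inf" if math.isinf(self.low) else ("[" if self.low_inclusive else "(") + _fmt(self.low)
        hi = "inf)" if math.isinf(self.high) else _fmt(self.high) + ("]" if self.high_inclusive else ")")
        return f"{lo}, {hi}"


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass(frozen=True)
class IntervalScheme:
    """Ordered intervals for one attribute plus the gap-closed cut-points.

    ``cuts`` is a tuple of ``(value, equal_goes_right)`` pairs: a value equal
    to the cut maps to the interval above it iff the flag is set (i.e. the
    upper interval is lower-inclusive at that cut).
    """

    attribute: str
    intervals: tuple
    cuts: tuple
    source: str = ""

    def __post_init__(self):
        assert [iv.code for iv in self.intervals] == list(range(len(self.intervals)))
        assert len(self.cuts) == len(self.intervals) - 1

    def code_for(self, x: float) -> int:
        if not math.isfinite(x):
            raise DiscretizationError(f"{self.attribute}: non-finite value {x}")
        code = 0
        for c, equal_right in self.cuts:
            if x > c or (x == c and equal_right):
                code += 1
            else:
                break
        return code

    def interval_for(self, x: float) -> SemanticInterval:
        return self.intervals[self.code_for(x)]

    def code_map(self) -> dict:
        return {iv.code: str(iv) for iv in self.intervals}

    def label_for(self, x: float) -> str:
        return self.interval_for(x).label


def _parse_interval(text: str, code: int, label: str) -> SemanticInterval:
    body = text.strip()
    lo_inc = body[0] == "["
    hi_inc = body[-1] == "]"
    lo_s, hi_s = body[1:-1].split(",")
    lo = -math.inf if "inf" in lo_s else float(lo_s)
    hi = math.inf if "inf" in hi_s else float(hi_s)
    return SemanticInterval(lo, hi, lo_inc, hi_inc, code, label)


def _scheme(attribute, intervals, labels, cuts, source):
    ivs = tuple(
        _parse_interval(t, i, lab) for i, (t, lab) in enumerate(zip(intervals, labels))
    )
    return IntervalScheme(attribute, ivs, tuple(cuts), source)


def builtin_schemes() -> dict:
    """Guideline discretization schemes for the twelve continuous clinical
    attributes.  Gender is nominal and has no scheme."""
    return {s.attribute: s for s in [
        _scheme("BMI",
                ["(-inf, 18.5)", "[18.5, 24.9]", "[25, 30)", "[30, inf)"],
                ["underweight", "normal", "overweight", "obese"],
                [(18.5, True), (25.0, True), (30.0, True)],
                "WHO BMI classification"),
        _scheme("Age",
                ["(-inf, 30)", "[30, 50]", "(50, inf)"],
                ["under 30", "30 to 50", "over 50"],
                [(30.0, True), (50.0, False)],
                "cohort-defined"),
        _scheme("SBP",
                ["(-inf, 120)", "[120, 139]", "[140, 159]", "[160, 180]", "[181, inf)"],
                ["normal", "prehypertension", "hypertension stage 1",
                 "hypertension stage 2", "hypertensive crisis"],
                [(120.0, True), (140.0, True), (160.0, True), (181.0, True)],
                "JNC 7 report, AHA"),
        _scheme("DBP",
                ["(-inf, 80)", "[80, 89]", "[90, 99]", "[100, 110]", "(110, inf)"],
                ["normal", "prehypertension", "hypertension stage 1",
                 "hypertension stage 2", "hypertensive crisis"],
                [(80.0, True), (90.0, True), (100.0, True), (110.0, False)],
                "JNC 7 report, AHA"),
        _scheme("FBS",
                ["(-inf, 70)", "[70, 99]", "(99, 126]", "(126, inf)"],
                ["hypoglycemia", "normal", "pre-diabetic", "diabetic"],
                [(70.0, True), (99.0, False), (126.0, False)],
                "ADA"),
        _scheme("Hba1c",
                ["[4, 5.9]", "(5.9, 6.4]", "(6.4, 7.4]", "(7.4, inf)"],
                ["hypoglycemia", "prediabetes", "diabetes", "diabetes with higher risk"],
                [(5.9, False), (6.4, False), (7.4, False)],
                "ADA, NICE"),
        _scheme("TC",
                ["(-inf, 200)", "[200, 239]", "[240, inf)"],
                ["desirable", "borderline high", "high"],
                [(200.0, True), (240.0, True)],
                "NCEP, ADA"),
        _scheme("TG",
                ["(-inf, 150)", "[150, 199]", "[200, 499]", "[500, inf)"],
                ["normal", "borderline-high", "high", "very high"],
                [(150.0, True), (200.0, True), (500.0, True)],
                "NCEP, ADA"),
        _scheme("HDL",
                ["(-inf, 40)", "[40, 60)", "[60, inf)"],
                ["low", "normal", "high"],
                [(40.0, True), (60.0, True)],
                "NCEP, ADA"),
        _scheme("LDL",
                ["(-inf, 100)", "[100, 129]", "(129, 159]", "(159, 189]", "(189, inf)"],
                ["optimal", "near or above optimal", "borderline high", "high", "very high"],
                [(100.0, True), (129.0, False), (159.0, False), (189.0, False)],
                "NCEP, ADA"),
        _scheme("AST",
                ["(-inf, 5)", "[5, 40]", "(40, inf)"],
                ["low", "normal", "high"],
                [(5.0, True), (40.0, False)],
                "liver enzyme reference range"),
        _scheme("ALT",
                ["(-inf, 7)", "[7, 56]", "[57, inf)"],
                ["low", "normal", "high"],
                [(7.0, True), (57.0, True)],
                "liver enzyme reference range"),
    ]}


def discretize_value(scheme: IntervalScheme, x: float) -> SemanticInterval:
    """The unique interval containing x under the gap-closed tiling."""
    return scheme.interval_for(x)


def discretize_table(table: DecisionTable, schemes: dict | None = None,
                     force: bool = False) -> DecisionTable:
    """Replace continuous condition attributes by their interval codes.

    Nominal attributes and the decision pass through unchanged.  The output
    table is flagged discrete and carries a code -> printed-interval sidecar
    per attribute for rule rendering.
    """
    if table.discrete and not force:
        raise DiscretizationError("table already discrete; pass force=True to re-code")
    schemes = builtin_schemes() if schemes is None else schemes
    out = table.copy()
    maps = {}
    for attr in out.attributes:
        if attr.role != "condition" or attr.kind != "continuous":
            continue
        scheme = schemes.get(attr.name)
        if scheme is None:
            raise DiscretizationError(
                f"continuous attribute {attr.name!r} has no interval scheme "
                f"and is not declared nominal"
            )
        lo = min(iv.low for iv in scheme.intervals if math.isfinite(iv.low))
        hi = max(iv.high for iv in scheme.intervals if math.isfinite(iv.high))
        for r in out.records:
            v = r.values.get(attr.name, MISSING)
            if v is MISSING:
                raise DiscretizationError(
                    f"MISSING {attr.name} for patient {r.pid}; impute first")
            if v < lo - 10 * max(1.0, abs(lo)) or v > hi + 10 * max(1.0, abs(hi)):
                warnings.warn(
                    f"{attr.name}={v} far outside physiological range; mapped "
                    f"by the open-ended extreme interval")
            r.values[attr.name] = scheme.code_for(float(v))
        maps[attr.name] = scheme.code_map()
    out.discrete = True
    out.interval_maps = maps
    return out
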