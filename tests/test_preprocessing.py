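"""Composite splitting, the 20% attribute-drop rule and the three-tier
missing-value imputation protocol."""

import pytest

from roughdx.data_model import (MISSING, AttributeSpec, DecisionTable,
                                EncounterRecord, missingness_profile)
from roughdx.preprocessing import (PreprocessingError, drop_high_missing,
                                   impute, preprocess, split_composites)

from _helpers import make_table


def patient_table(seqs, decision_by_pid, attr="FBS", kind="continuous"):
    """Table with one attribute; seqs maps pid -> list of values (MISSING
    allowed)."""
    attrs = [AttributeSpec(attr, kind, "condition"),
             AttributeSpec("d", "nominal", "decision")]
    records = []
    for pid, seq in seqs.items():
        for i, v in enumerate(seq, start=1):
            records.append(EncounterRecord(
                pid=pid, encounter_id=i,
                values={attr: v, "d": decision_by_pid[pid]}))
    return DecisionTable(attributes=attrs, records=records)


class TestSplitComposites:
    def test_bp_split(self):
        t = make_table([{"BP": "120/80", "d": "X"}], discrete=False)
        out = split_composites(t)
        assert out.records[0].values == {"SBP": 120.0, "DBP": 80.0, "d": "X"}
        assert [a.name for a in out.attributes][:2] == ["SBP", "DBP"]

    def test_lipids_split(self):
        t = make_table([{"Lipids": "169/101/64/82", "d": "X"}], discrete=False)
        v = split_composites(t).records[0].values
        assert (v["TC"], v["TG"], v["HDL"], v["LDL"]) == (169.0, 101.0, 64.0, 82.0)

    def test_missing_composite_propagates(self):
        t = make_table([{"BP": MISSING, "d": "X"}], discrete=False)
        v = split_composites(t).records[0].values
        assert v["SBP"] is MISSING and v["DBP"] is MISSING

    def test_idempotent_on_split_table(self):
        t = make_table([{"SBP": 120, "DBP": 80, "d": "X"}], discrete=False)
        assert split_composites(t) is t

    def test_wrong_part_count_names_cell(self):
        t = make_table([{"BP": "120/80/60", "d": "X"}], discrete=False)
        with pytest.raises(PreprocessingError, match="BP"):
            split_composites(t)


class TestDropHighMissing:
    def _table(self, frac, n=100):
        k = int(round(frac * n))
        attrs = [AttributeSpec("FBS", "continuous", "condition"),
                 AttributeSpec("Age", "continuous", "condition"),
                 AttributeSpec("d", "nominal", "decision")]
        records = [
            EncounterRecord(pid="P1", encounter_id=i + 1,
                            values={"FBS": MISSING if i < k else 100.0,
                                    "Age": 40.0, "d": "X"})
            for i in range(n)
        ]
        return DecisionTable(attributes=attrs, records=records)

    def test_at_25_percent_dropped(self):
        out, rep = drop_high_missing(self._table(0.25))
        assert "FBS" not in out.condition_attributes
        assert "FBS" in rep.dropped_attributes

    def test_at_19_percent_retained(self):
        out, rep = drop_high_missing(self._table(0.19))
        assert rep.dropped_attributes == {}
        assert "FBS" in out.condition_attributes

    def test_exactly_20_percent_dropped(self):
        _, rep = drop_high_missing(self._table(0.20))
        assert "FBS" in rep.dropped_attributes

    def test_fully_observed_unchanged(self):
        t = self._table(0.0)
        out, rep = drop_high_missing(t)
        assert rep.dropped_attributes == {} and rep.filled_cells == []
        assert out.condition_attributes == t.condition_attributes

    def test_cannot_drop_all_condition_attributes(self):
        t = self._table(1.0)
        for r in t.records:
            r.values["Age"] = MISSING
        with pytest.raises(PreprocessingError):
            drop_high_missing(t)


class TestImpute:
    def test_consecutive_pair_prev_then_next(self):
        seq = [100, 102, MISSING, MISSING, 110, 112, 114, 116]
        t = patient_table({"P1": seq}, {"P1": "X"})
        out, rep = impute(t)
        vals = [r.values["FBS"] for r in out.records]
        assert vals[2] == 102 and vals[3] == 110
        strategies = {(e[1], e[3]) for e in rep.filled_cells}
        assert strategies == {(3, "prev"), (4, "next")}

    def test_nonconsecutive_prefers_previous(self):
        seq = [100, MISSING, 104, MISSING, 108]
        t = patient_table({"P1": seq}, {"P1": "X"})
        out, _ = impute(t)
        vals = [r.values["FBS"] for r in out.records]
        assert vals[1] == 100 and vals[3] == 104

    def test_first_encounter_uses_next(self):
        seq = [MISSING, 104, 108]
        out, rep = impute(patient_table({"P1": seq}, {"P1": "X"}))
        assert out.records[0].values["FBS"] == 104
        assert rep.filled_cells[0][3] == "next"

    def test_count_rule_dominates_patient_rate(self):
        # 2 of 4 missing is 50% but the count rule (<=2) still applies
        seq = [100, MISSING, MISSING, 120]
        out, rep = impute(patient_table({"P1": seq}, {"P1": "X"}))
        vals = [r.values["FBS"] for r in out.records]
        assert vals[1] == 100 and vals[2] == 120
        assert {e[3] for e in rep.filled_cells} == {"prev", "next"}

    def test_patient_average_rule(self):
        seq = [float(i) for i in range(1, 18)] + [MISSING] * 3   # 3/20 = 15%
        out, rep = impute(patient_table({"P1": seq}, {"P1": "X"}))
        expected = sum(range(1, 18)) / 17
        for r in out.records[17:]:
            assert r.values["FBS"] == pytest.approx(expected)
        assert all(e[3] == "patient_average" for e in rep.filled_cells)

    def test_class_average_fallback_hand_computed(self):
        # patient P1 missing 3/4 (>20%) -> class mean over class-X records
        seqs = {"P1": [MISSING, MISSING, MISSING, 100.0],
                "P2": [110.0, 130.0]}
        t = patient_table(seqs, {"P1": "X", "P2": "X"})
        out, rep = impute(t)
        expected = (100.0 + 110.0 + 130.0) / 3
        for r in out.records[:3]:
            assert r.values["FBS"] == pytest.approx(expected)
        assert all(e[3] == "class_average" for e in rep.filled_cells)

    def test_single_encounter_patient_falls_back_to_class(self):
        t = patient_table({"P1": [MISSING], "P2": [50.0, 70.0]},
                          {"P1": "X", "P2": "X"})
        out, rep = impute(t)
        assert out.records[0].values["FBS"] == pytest.approx(60.0)
        assert rep.filled_cells[0][3] == "class_average"

    def test_nominal_mode_tie_breaks_earliest(self):
        # 3 of 20 missing (15%) -> patient-frequent rule; b ties a (2 each),
        # b observed first
        seqs = {"P1": ["b", "a", "b", "a", MISSING, MISSING, MISSING,
                       "c", "x", "y", "z", "q", "r", "s", "t", "u", "v",
                       "w", "k", "l"]}
        t = patient_table(seqs, {"P1": "X"}, attr="G", kind="nominal")
        out, rep = impute(t)
        assert all(e[3] == "patient_frequent" for e in rep.filled_cells)
        assert out.records[4].values["G"] == "b"

    def test_attribute_missing_for_entire_class_errors(self):
        t = patient_table({"P1": [MISSING, MISSING, MISSING]}, {"P1": "X"})
        with pytest.raises(PreprocessingError):
            impute(t)

    def test_idempotent_on_complete_table(self):
        t = patient_table({"P1": [1.0, 2.0]}, {"P1": "X"})
        out, rep = impute(t)
        assert rep.filled_cells == []
        assert [r.values for r in out.records] == [r.values for r in t.records]


class TestEndToEnd:
    def test_synthetic_completeness_and_conservatism(self, dmis):
        before = missingness_profile(dmis)
        n = dmis.n_records
        n_missing_retained = sum(
            round(before[a] * n) for a in before
            if a not in ("FHx", "SHx", "TDM") and before[a] < 0.20)
        clean, rep = preprocess(dmis)
        assert set(rep.dropped_attributes) == {"FHx", "SHx"}
        prof = missingness_profile(clean)
        assert all(v == 0.0 for v in prof.values())
        assert len(rep.filled_cells) == n_missing_retained
        # observed cells never altered
        for r_old, r_new in zip(dmis.records, clean.records):
            for k, v in r_old.values.items():
                if v is not MISSING and k in r_new.values:
                    assert r_new.values[k] == v
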