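"""Model/Results facade over the full pipeline.

:class:`DiabetesRuleModel` is built from raw encounter data (a
:class:`~roughdx.data_model.DecisionTable`, a pandas DataFrame or a CSV
file).  ``fit()`` runs preprocessing (composite splitting, attribute
dropping, imputation), guideline discretization, the reduct/core search and
LEM2 rule induction, and returns a :class:`DiabetesRuleResults` carrying the
rule set, reduct bookkeeping and diagnostics, with ``summary()``,
``predict()``, ``cross_validate()``, ``interpret()`` and ``trend()``.
"""

from __future__ import annotations

import pandas as pd

from . import preprocessing
from .classify import ClassifierParams, classify, kfold_cv
from .data_model import (DecisionTable, EncounterRecord, class_counts,
                         read_table)
from .discretization import builtin_schemes, discretize_table
from .reasoning import apply_hrbr, discretize_encounter, perform_3r
from .roughset import find_all_reducts
from .rules import induce_rules
from .trend import ObservationSeries, fit_trend, forecast


class DiabetesRuleModel:
    """Rough-set rule model for diabetes type prediction.

    Parameters
    ----------
    table:
        Raw decision table of per-encounter records.
    schemes:
        Interval schemes for discretization; defaults to the built-in
        guideline schemes.
    drop_threshold:
        Dataset-level missingness fraction at or above which a condition
        attribute is dropped (default 0.20).
    params:
        LERS classification parameters used by ``predict`` and
        ``cross_validate``.
    """

    def __init__(self, table: DecisionTable, schemes: dict | None = None,
                 drop_threshold: float = 0.20,
                 params: ClassifierParams | None = None):
        self.table = table
        self.schemes = schemes or builtin_schemes()
        self.drop_threshold = drop_threshold
        self.params = params or ClassifierParams()

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, decision: str = "TDM",
                       **kwargs) -> "DiabetesRuleModel":
        import os
        import tempfile
        fd, path = tempfile.mkstemp(suffix=".csv")
        try:
            with os.fdopen(fd, "w") as fh:
                df.to_csv(fh, index=False)
            table = read_table(path, decision=decision)
        finally:
            os.unlink(path)
        return cls(table, **kwargs)

    @classmethod
    def from_csv(cls, path, decision: str = "TDM", **kwargs) -> "DiabetesRuleModel":
        return cls(read_table(path, decision=decision), **kwargs)

    # -- fitting ---------------------------------------------------------
    def fit(self, attrs: str = "core") -> "DiabetesRuleResults":
        clean, report = preprocessing.preprocess(self.table, self.drop_threshold)
        discrete = discretize_table(clean, self.schemes)
        reduct_set = find_all_reducts(discrete)
        rules = induce_rules(discrete, attrs=attrs)
        return DiabetesRuleResults(
            model=self, clean_table=clean, discrete_table=discrete,
            imputation_report=report, reduct_set=reduct_set, rules=rules,
            attrs=attrs)


class DiabetesRuleResults:
    """Fitted rule set plus diagnostics."""

    def __init__(self, model, clean_table, discrete_table, imputation_report,
                 reduct_set, rules, attrs):
        self.model = model
        self.clean_table = clean_table
        self.discrete_table = discrete_table
        self.imputation_report = imputation_report
        self.reduct_set = reduct_set
        self.rules = rules
        self.attrs = attrs

    # -- inference -------------------------------------------------------
    def predict(self, encounter, raw: bool = True):
        """Classify one encounter (dict or EncounterRecord); raw values are
        discretized through the model's schemes first."""
        values = encounter.values if isinstance(encounter, EncounterRecord) else dict(encounter)
        if raw:
            values = discretize_encounter(values, self.model.schemes)
        return classify(values, self.rules, self.model.params)

    def interpret(self, encounter) -> dict:
        """Reference-range interpretation of raw observations."""
        return perform_3r(encounter)

    def reason(self, encounter, registered: bool = False, mode: str = "first_match"):
        """Full online reasoning: prediction + interpretation, or routing to
        trend analysis for registered patients."""
        return apply_hrbr(encounter, registered, self.rules,
                          mode=mode, params=self.model.params,
                          schemes=self.model.schemes)

    def cross_validate(self, k: int = 10, seed: int = 0, **kwargs):
        return kfold_cv(self.discrete_table, k=k, seed=seed,
                        params=self.model.params, attrs=self.attrs, **kwargs)

    def trend(self, pid: str, attribute: str, degree: int = 3, horizon: int = 3):
        series = ObservationSeries.from_table(self.clean_table, pid, attribute)
        tm = fit_trend(series, degree)
        forecast(tm, horizon)
        return tm

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        t = self.discrete_table
        counts = class_counts(t)
        lines = []
        lines.append("Rough-set diabetes rule model")
        lines.append("=" * 64)
        lines.append(f"records: {t.n_records}   classes: " +
                     ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
        if self.imputation_report.dropped_attributes:
            lines.append("dropped attributes: " +
                         ", ".join(sorted(self.imputation_report.dropped_attributes)))
        lines.append(f"imputed cells: {len(self.imputation_report.filled_cells)}")
        lines.append(f"reducts found: {len(self.reduct_set.reducts)}")
        lines.append("core: {" + ", ".join(sorted(self.reduct_set.core)) + "}")
        lines.append(f"rules ({len(self.rules.rules)} total, "
                     f"{len(self.rules.approximate)} approximate), induced on "
                     f"{'core' if self.attrs == 'core' else self.attrs} attributes:")
        lines.append("-" * 64)
        for i, r in enumerate(self.rules.rules, 1):
            lines.append(f"{i:>3}. " + r.render(self.rules.scheme_snapshot,
                                                self.rules.training_class_sizes))
        return "\n".join(lines)
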