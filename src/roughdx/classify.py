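"""LERS-style rule classification, stratified k-fold cross-validation and
the evaluation metrics (per-fold percent accuracy, average accuracy and
error, pooled confusion matrix, balanced accuracy).

Classification votes in two stages.  Stage 1 considers rules whose every
condition is satisfied; each covered class accrues the rule's strength.
If nothing matches fully and partial matching is enabled, stage 2 lets rules
with similarity (matched conditions / total conditions) >= the minimum
similarity accrue strength x similarity.  The winning class must hold a
share of the total accrued support above the majority threshold, otherwise
the record is left unclassified ("None").
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import DecisionTable, EncounterRecord
from .rules import RuleSet, induce_rules


class EvaluationError(ValueError):
    pass


UNCLASSIFIED = "None"


@dataclass(frozen=True)
class ClassifierParams:
    majority_threshold: float = 0.21
    min_similarity: float = 0.50
    partial_matching: str = "all"     # all | none
    unmatched_label: str = UNCLASSIFIED

    def __post_init__(self):
        if not (0 <= self.majority_threshold <= 1):
            raise EvaluationError("majority_threshold outside [0, 1]")
        if not (0 <= self.min_similarity <= 1):
            raise EvaluationError("min_similarity outside [0, 1]")
        if self.partial_matching not in ("all", "none"):
            raise EvaluationError("partial_matching must be 'all' or 'none'")


def _accrue(scores: dict, rule, weight: float = 1.0) -> None:
    for cls, s in rule.class_support.items():
        scores[cls] = scores.get(cls, 0.0) + s * weight


def classify(record, rules: RuleSet, params: ClassifierParams | None = None):
    """Classify one discrete record; returns a class label or "None"."""
    params = params or ClassifierParams()
    values = record.values if isinstance(record, EncounterRecord) else dict(record)

    scores: dict = {}
    for rule in rules.rules:
        if rule.matches(values):
            _accrue(scores, rule)
    if not scores and params.partial_matching == "all":
        for rule in rules.rules:
            sim = rule.similarity(values)
            if sim >= params.min_similarity:
                _accrue(scores, rule, weight=sim)
    total = sum(scores.values())
    if total <= 0:
        return params.unmatched_label
    priors = rules.training_class_sizes
    winner = max(scores, key=lambda c: (scores[c], priors.get(c, 0), str(c)))
    if scores[winner] / total <= params.majority_threshold:
        return params.unmatched_label
    return winner


@dataclass
class ConfusionMatrix:
    """Counts keyed by (true class, predicted label); predictions may be
    "None" for unclassified records."""

    counts: dict = field(default_factory=dict)

    def add(self, true, pred, n: int = 1) -> None:
        self.counts[(true, pred)] = self.counts.get((true, pred), 0) + n

    def merge(self, other: "ConfusionMatrix") -> None:
        for k, n in other.counts.items():
            self.counts[k] = self.counts.get(k, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def true_classes(self):
        return sorted({t for t, _ in self.counts}, key=str)

    def class_total(self, cls) -> int:
        return sum(n for (t, _), n in self.counts.items() if t == cls)

    def correct(self) -> int:
        return sum(n for (t, p), n in self.counts.items() if t == p)

    def binary(self, positive):
        """(TP, FN, FP, TN) treating every non-positive prediction on a
        positive record as FN and symmetrically for negatives."""
        tp = self.counts.get((positive, positive), 0)
        fn = self.class_total(positive) - tp
        fp = sum(n for (t, p), n in self.counts.items()
                 if t != positive and p == positive)
        tn = sum(self.class_total(c) for c in self.true_classes()
                 if c != positive) - fp
        return tp, fn, fp, tn


def balanced_accuracy(cm: ConfusionMatrix, positive) -> float:
    """0.5 * sensitivity + 0.5 * specificity for the designated positive
    class."""
    tp, fn, fp, tn = cm.binary(positive)
    if tp + fn == 0 or tn + fp == 0:
        raise EvaluationError("balanced accuracy needs both classes populated")
    return 0.5 * tp / (tp + fn) + 0.5 * tn / (tn + fp)


def average_accuracy(fold_accuracies) -> float:
    """Arithmetic mean of per-fold percent accuracies, unrounded."""
    accs = list(fold_accuracies)
    if not accs:
        raise EvaluationError("no fold accuracies")
    return sum(accs) / len(accs)


@dataclass
class CVReport:
    fold_sizes: list
    fold_correct: list
    fold_incorrect: list
    fold_accuracy: list           # percent, exact 100*correct/size
    fold_error: list              # percent
    confusion: ConfusionMatrix
    average_accuracy: float
    average_error: float
    std_error_of_fold_errors: float
    per_class_accuracy: dict      # pooled, percent
    balanced_accuracy: float | None
    seed: int
    k: int

    def summary(self) -> str:
        lines = ["pass  size  incorrect  correct  %accuracy   %error"]
        for i in range(self.k):
            lines.append(
                f"{i + 1:>4}  {self.fold_sizes[i]:>4}  {self.fold_incorrect[i]:>9}"
                f"  {self.fold_correct[i]:>7}  {self.fold_accuracy[i]:>9.4f}"
                f"  {self.fold_error[i]:>7.4f}")
        lines.append(
            f"average accuracy {self.average_accuracy:.8f}  "
            f"average error {self.average_error:.8f}  "
            f"sd(fold errors) {self.std_error_of_fold_errors:.4f}")
        if self.balanced_accuracy is not None:
            lines.append(f"balanced accuracy {self.balanced_accuracy:.4f}")
        return "\n".join(lines)


def stratified_folds(table: DecisionTable, k: int, seed: int,
                     stratified: bool = True) -> list:
    """Fold assignment: fold sizes differ by at most one; with
    stratification each class is spread across folds by largest remainder."""
    n = table.n_records
    if k < 2:
        raise EvaluationError("k must be >= 2")
    if n < k:
        raise EvaluationError("fewer records than folds")
    rng = np.random.default_rng(seed)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    folds = [[] for _ in range(k)]
    if not stratified:
        perm = list(rng.permutation(n))
        pos = 0
        for i, s in enumerate(sizes):
            folds[i] = perm[pos:pos + s]
            pos += s
        return [sorted(int(j) for j in f) for f in folds]

    decisions = table.decisions()
    by_class: dict = {}
    for i, d in enumerate(decisions):
        by_class.setdefault(d, []).append(i)
    quota = [[0] * k for _ in range(len(by_class))]
    capacity = list(sizes)
    for ci, cls in enumerate(sorted(by_class, key=str)):
        c = len(by_class[cls])
        base = c // k
        rem = c - base * k
        for f in range(k):
            quota[ci][f] = base
            capacity[f] -= base
        # hand out remainders to the folds with most spare capacity
        order = sorted(range(k), key=lambda f: (-capacity[f], f))
        for f in order[:rem]:
            quota[ci][f] += 1
            capacity[f] -= 1
    for ci, cls in enumerate(sorted(by_class, key=str)):
        idx = list(rng.permutation(by_class[cls]))
        pos = 0
        for f in range(k):
            folds[f].extend(idx[pos:pos + quota[ci][f]])
            pos += quota[ci][f]
    return [sorted(int(j) for j in f) for f in folds]


def kfold_cv(table: DecisionTable, k: int = 10,
             params: ClassifierParams | None = None, seed: int = 0,
             attrs: str | list = "core", stratified: bool = True,
             positive=None) -> CVReport:
    """k-fold cross-validation: per fold, induce rules on the training split
    and classify the held-out records; deterministic for a fixed seed."""
    params = params or ClassifierParams()
    folds = stratified_folds(table, k, seed, stratified)
    all_classes = set(table.decision_domain)
    pooled = ConfusionMatrix()
    fold_sizes, fold_correct, fold_incorrect = [], [], []
    fold_acc, fold_err = [], []
    for f in range(k):
        test_idx = folds[f]
        train_idx = [i for g in range(k) if g != f for i in folds[g]]
        train = table.subset(train_idx)
        if set(train.decision_domain) != all_classes:
            warnings.warn(f"fold {f + 1}: a class is absent from the training split")
        ruleset = induce_rules(train, attrs=attrs)
        correct = 0
        for i in test_idx:
            rec = table.records[i]
            pred = classify(rec, ruleset, params)
            true = rec.values[table.decision_attribute]
            pooled.add(true, pred)
            if pred == true:
                correct += 1
        size = len(test_idx)
        fold_sizes.append(size)
        fold_correct.append(correct)
        fold_incorrect.append(size - correct)
        fold_acc.append(100.0 * correct / size)
        fold_err.append(100.0 * (size - correct) / size)

    per_class = {
        cls: 100.0 * pooled.counts.get((cls, cls), 0) / pooled.class_total(cls)
        for cls in pooled.true_classes()
    }
    bal = None
    if positive is None and len(all_classes) == 2:
        positive = min(all_classes, key=lambda c: table.decisions().count(c))
    if positive is not None:
        bal = balanced_accuracy(pooled, positive)
    return CVReport(
        fold_sizes=fold_sizes,
        fold_correct=fold_correct,
        fold_incorrect=fold_incorrect,
        fold_accuracy=fold_acc,
        fold_error=fold_err,
        confusion=pooled,
        average_accuracy=average_accuracy(fold_acc),
        average_error=average_accuracy(fold_err),
        std_error_of_fold_errors=statistics.stdev(fold_err) if k > 1 else 0.0,
        per_class_accuracy=per_class,
        balanced_accuracy=bal,
        seed=seed,
        k=k,
    )
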