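"""Interpretable if-then rules with certainty grades.

A binary decision tree (entropy split criterion) is grown on the mined
descriptor subset; every root-to-leaf path becomes a threshold rule over
named descriptors, graded by a Laplace-corrected leaf confidence
CF = (correct + 1) / (covered + 2).  Rules are ordered by descending CF
and applied first-match-wins, with a default class for uncovered inputs.
Conditions use the "<= t" / "> t" convention: a value exactly on the
threshold takes the <= branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .seqio import NEGATIVE, POSITIVE

CLASS_NAMES = {POSITIVE: "promoter", NEGATIVE: "nonpromoter"}


@dataclass(frozen=True)
class Condition:
    feature: str
    op: str  # "<=" or ">"
    threshold: float

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.op == "<=" else value > self.threshold

    def __str__(self) -> str:
        return f"{self.feature} {self.op} {self.threshold:g}"


@dataclass(frozen=True)
class Rule:
    conditions: tuple[Condition, ...]
    predicted_class: int
    cf: float
    coverage: int

    def matches(self, values: Mapping[str, float]) -> bool:
        for cond in self.conditions:
            if cond.feature not in values:
                raise KeyError(
                    f"descriptor {cond.feature!r} missing from input vector")
            if not cond.holds(values[cond.feature]):
                return False
        return True

    def __str__(self) -> str:
        conds = " and ".join(str(c) for c in self.conditions)
        return (f"if {conds} then {CLASS_NAMES[self.predicted_class]} "
                f"[CF {self.cf:.3f}]")


@dataclass
class RuleSet:
    rules: list[Rule]
    default_class: int
    feature_names: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [f"R{i + 1}: {rule}" for i, rule in enumerate(self.rules)]
        lines.append(f"default: {CLASS_NAMES[self.default_class]}")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "default_class": self.default_class,
            "feature_names": self.feature_names,
            "rules": [
                {"conditions": [asdict(c) for c in r.conditions],
                 "predicted_class": r.predicted_class,
                 "cf": r.cf, "coverage": r.coverage}
                for r in self.rules
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RuleSet":
        d = json.loads(Path(path).read_text())
        rules = [
            Rule(tuple(Condition(**c) for c in r["conditions"]),
                 r["predicted_class"], r["cf"], r["coverage"])
            for r in d["rules"]
        ]
        return cls(rules, d["default_class"], d.get("feature_names", []))


def induce_rules(X: np.ndarray, y: np.ndarray,
                 feature_names: Sequence[str],
                 max_depth: int = 4, min_leaf: int = 10) -> RuleSet:
    """Grow an entropy-criterion tree on the selected-feature matrix and
    convert each root-to-leaf path into a graded rule.

    Single-class input yields an empty rule list whose default class is
    that class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    names = list(feature_names)
    if X.shape[1] != len(names):
        raise ValueError("feature_names length must match matrix width")
    classes = np.unique(y)
    majority = int(classes[np.argmax([np.sum(y == c) for c in classes])])
    if classes.size < 2:
        return RuleSet([], default_class=majority, feature_names=names)

    tree = DecisionTreeClassifier(criterion="entropy", max_depth=max_depth,
                                  min_samples_leaf=min_leaf, random_state=0)
    tree.fit(X, y)
    t = tree.tree_

    rules: list[Rule] = []

    def walk(node: int, conds: list[Condition]) -> None:
        if t.children_left[node] == -1:  # leaf
            counts = t.value[node][0] * t.weighted_n_node_samples[node]
            counts = np.rint(counts).astype(int)
            covered = int(counts.sum())
            cls_idx = int(np.argmax(counts))
            correct = int(counts[cls_idx])
            cf = (correct + 1) / (covered + 2)
            predicted = int(tree.classes_[cls_idx])
            if conds:
                rules.append(Rule(tuple(conds), predicted, cf, covered))
            return
        feat = names[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], conds + [Condition(feat, "<=", thr)])
        walk(t.children_right[node], conds + [Condition(feat, ">", thr)])

    walk(0, [])
    rules.sort(key=lambda r: (-r.cf, len(r.conditions)))
    return RuleSet(rules, default_class=majority, feature_names=names)


def apply_rules(ruleset: RuleSet, vector: Mapping[str, float] | np.ndarray
                ) -> tuple[int, int | None]:
    """Classify one (scaled) descriptor vector: the first rule whose
    conditions all hold fires; otherwise the default class.

    Returns (class, 1-based fired rule index or None for the default).
    """
    if not isinstance(vector, Mapping):
        arr = np.asarray(vector, dtype=float).ravel()
        if arr.size != len(ruleset.feature_names):
            raise ValueError(
                f"vector length {arr.size} != rule set feature count "
                f"{len(ruleset.feature_names)}")
        vector = dict(zip(ruleset.feature_names, arr))
    for i, rule in enumerate(ruleset.rules):
        if rule.matches(vector):
            return rule.predicted_class, i + 1
    return ruleset.default_class, None


def cumulative_accuracy(ruleset: RuleSet, X: np.ndarray, y: np.ndarray
                        ) -> list[tuple[int, float]]:
    """Accuracy of each rule-list prefix, counting instances matched by no
    prefix rule as unclassified-incorrect."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    vectors = [dict(zip(ruleset.feature_names, row)) for row in X]
    # first matching rule index per instance (None if uncovered)
    first_match: list[int | None] = []
    for v in vectors:
        hit = None
        for i, rule in enumerate(ruleset.rules):
            if rule.matches(v):
                hit = i
                break
        first_match.append(hit)
    table = []
    for prefix in range(1, len(ruleset.rules) + 1):
        correct = sum(
            1 for hit, label in zip(first_match, y)
            if hit is not None and hit < prefix
            and ruleset.rules[hit].predicted_class == label)
        table.append((prefix, correct / len(y)))
    return table
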