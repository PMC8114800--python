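"""Classification of new instances.

Crisp mode (the default, and the one the evaluation protocol uses) traverses
the tree on an instance's linguistic labels.  Soft mode scores every
extracted rule against a raw numeric instance by compatibility degree — the
t-norm (min by default) of the instance's membership degrees in the rule's
antecedent fuzzy sets — and predicts the class of the best rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .membership import FuzzyDatabase, membership_degree
from .tree import DecisionNode, FuzzyRule

TNorm = Literal["min", "product"]


@dataclass(frozen=True)
class Prediction:
    """A classified instance: the class, the rule that produced it (crisp
    traversal implicitly follows one rule), and its compatibility degree."""

    predicted_class: str
    matched_rule: FuzzyRule | None = None
    compatibility: float = 1.0


def classify_crisp(tree: DecisionNode, instance: Mapping[str, str]) -> Prediction:
    """Deterministic root-to-leaf traversal on the instance's labels.

    Branch completeness at induction guarantees a leaf is always reached;
    an instance label outside the split attribute's partition is an error.
    """
    node = tree
    while not node.is_leaf:
        label = instance[node.attribute]
        if label not in node.branches:
            raise KeyError(
                f"label {label!r} is not in the partition of attribute "
                f"{node.attribute!r}")
        node = node.branches[label]
    return Prediction(node.predicted_class, None, 1.0)


def predict_crisp_table(tree: DecisionNode, df) -> "np.ndarray":
    """Crisp predictions for every row of a linguistic DataFrame.

    Equivalent to :func:`classify_crisp` row by row, but routes whole index
    blocks down the tree at once.
    """
    preds = np.empty(len(df), dtype=object)
    pos = np.arange(len(df))

    def route(node: DecisionNode, rows: np.ndarray) -> None:
        if len(rows) == 0:
            return
        if node.is_leaf:
            preds[rows] = node.predicted_class
            return
        col = df[node.attribute].to_numpy()[rows]
        seen = set(col.tolist())
        unknown = seen - set(node.branches)
        if unknown:
            raise KeyError(
                f"labels {sorted(unknown)} are not in the partition of "
                f"attribute {node.attribute!r}")
        for label, child in node.branches.items():
            route(child, rows[col == label])

    route(tree, pos)
    return preds


def rule_compatibility(
    rule: FuzzyRule,
    raw_instance: Mapping[str, float],
    db: FuzzyDatabase,
    tnorm: TNorm = "min",
) -> float:
    """Compatibility degree of a raw instance with a rule's antecedents.

    Values are clamped to each attribute's universe before evaluation; an
    empty antecedent list is vacuously compatible (degree 1).
    """
    degree = 1.0
    for attr, label in rule.antecedents:
        if attr not in raw_instance:
            raise KeyError(f"instance is missing antecedent attribute {attr!r}")
        part = db[attr]
        mf = part.mfs[part.labels.index(label)]
        mu = membership_degree(mf, part.clamp(float(raw_instance[attr])))
        degree = min(degree, mu) if tnorm == "min" else degree * mu
        if degree == 0.0:
            break
    return degree


def classify_soft(
    rules: Sequence[FuzzyRule],
    raw_instance: Mapping[str, float],
    db: FuzzyDatabase,
    tnorm: TNorm = "min",
    default_class: str | None = None,
) -> Prediction:
    """Predict the class of the maximum-compatibility rule.

    Ties are broken by higher confidence, then fewer antecedents, then
    extraction order.  If every rule has compatibility 0 (possible only for
    clamped out-of-universe pathologies), fall back to ``default_class``.
    """
    if not rules:
        raise ValueError("empty rule list")
    best: FuzzyRule | None = None
    best_key: tuple | None = None
    best_compat = 0.0
    for order, rule in enumerate(rules):
        compat = rule_compatibility(rule, raw_instance, db, tnorm)
        if compat == 0.0:
            continue
        key = (compat, rule.confidence, -len(rule.antecedents), -order)
        if best_key is None or key > best_key:
            best, best_key, best_compat = rule, key, compat
    if best is None:
        fallback = default_class if default_class is not None else rules[0].consequent
        warnings.warn(
            "no rule has nonzero compatibility with the instance; "
            f"falling back to the majority class {fallback!r}", stacklevel=2)
        return Prediction(fallback, None, 0.0)
    return Prediction(best.consequent, best, best_compat)
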