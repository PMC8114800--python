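"""ID3 induction on a linguistic table, and rule extraction.

Classic recursive partitioning with Shannon entropy / information gain as the
attribute-selection criterion.  Because the training data are already
linguistic, every split creates one branch per label of the attribute's fuzzy
partition (not merely the labels seen in the node's subset), so crisp
inference is total.  No pruning is applied.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .fuzzify import LinguisticTable
from .membership import FuzzyDatabase


@dataclass(frozen=True)
class ClassDistribution:
    """Class counts at a node; proportions feed Shannon's entropy."""

    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def majority(self) -> str:
        # ties broken by lexicographically smallest label, deterministically
        best = max(self.counts.values())
        return min(c for c, n in self.counts.items() if n == best)


def class_entropy(dist: ClassDistribution | Mapping[str, int]) -> float:
    """Shannon entropy ``-sum p_i log2 p_i`` in bits (0·log0 := 0)."""
    counts = dist.counts if isinstance(dist, ClassDistribution) else dist
    n = sum(counts.values())
    if n <= 0:
        raise ValueError("entropy of an empty class distribution")
    p = np.array([c for c in counts.values() if c > 0], dtype=float) / n
    return float(-(p * np.log2(p)).sum())


def information_gain(
    table: LinguisticTable | pd.DataFrame,
    attribute: str,
    class_column: str = "class",
) -> float:
    """Expected entropy reduction from splitting on ``attribute``:
    ``Gain(S, A) = E(S) - sum_v |S_v|/|S| * E(S_v)`` over labels v in S."""
    df = table.df if isinstance(table, LinguisticTable) else table
    if isinstance(table, LinguisticTable):
        class_column = table.class_column
    if attribute not in df.columns or attribute == class_column:
        raise KeyError(f"unknown attribute {attribute!r}")
    n = len(df)
    parent = class_entropy(Counter(df[class_column]))
    child = 0.0
    for _, sub in df.groupby(attribute, observed=True):
        child += len(sub) / n * class_entropy(Counter(sub[class_column]))
    return parent - child


@dataclass
class DecisionNode:
    """A node of the induced tree.

    Internal nodes carry the split attribute and one child per partition
    label; leaves carry the predicted class.  Every node records the majority
    class and the count of training rows that reached it, so empty branches
    can fall back to their parent's majority.
    """

    kind: str  # "internal" | "leaf"
    majority_class: str
    support: int
    attribute: str | None = None
    branches: dict[str, "DecisionNode"] = field(default_factory=dict)
    predicted_class: str | None = None
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.kind == "leaf"

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(child.depth() for child in self.branches.values())

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return sum(child.n_leaves() for child in self.branches.values())

    def n_nodes(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + sum(child.n_nodes() for child in self.branches.values())

    def iter_leaves(self) -> Iterator["DecisionNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.branches.values():
                yield from child.iter_leaves()

    def to_dict(self) -> dict:
        d: dict = {
            "kind": self.kind,
            "majority_class": self.majority_class,
            "support": self.support,
        }
        if self.is_leaf:
            d["predicted_class"] = self.predicted_class
            d["class_counts"] = dict(self.class_counts)
        else:
            d["attribute"] = self.attribute
            d["branches"] = {lab: ch.to_dict() for lab, ch in self.branches.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DecisionNode":
        if d["kind"] == "leaf":
            return cls(
                kind="leaf",
                majority_class=d["majority_class"],
                support=int(d["support"]),
                predicted_class=d["predicted_class"],
                class_counts={c: int(n) for c, n in d.get("class_counts", {}).items()},
            )
        return cls(
            kind="internal",
            majority_class=d["majority_class"],
            support=int(d["support"]),
            attribute=d["attribute"],
            branches={lab: cls.from_dict(ch) for lab, ch in d["branches"].items()},
        )

    def to_json(self, path=None) -> str | None:
        text = json.dumps(self.to_dict(), indent=2)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def _domains_from_db(db: FuzzyDatabase) -> dict[str, tuple[str, ...]]:
    return {name: part.labels for name, part in db.partitions.items()}


def induce_tree(
    table: LinguisticTable,
    domains: FuzzyDatabase | Mapping[str, Sequence[str]],
    min_support: int = 1,
) -> DecisionNode:
    """Induce an ID3 tree on a linguistic table.

    At each node the attribute with maximal information gain is chosen (ties
    broken by column order); a branch is created for *every* label in the
    attribute's domain, with empty branches becoming leaves that predict the
    node's majority class.  Recursion terminates on class purity, attribute
    exhaustion, or empty subsets.  ``min_support`` (default 1, i.e. off)
    optionally turns nodes with fewer rows into leaves.

    A single-class table yields a single leaf (with a warning path handled by
    the caller); an empty table is an error.
    """
    if isinstance(domains, FuzzyDatabase):
        domains = _domains_from_db(domains)
    if table.n_rows == 0:
        raise ValueError("cannot induce a tree from an empty table")
    df = table.df
    class_column = table.class_column
    attrs = [a for a in table.attributes if a in domains]
    if set(attrs) != set(table.attributes):
        missing = set(table.attributes) - set(attrs)
        raise KeyError(f"attributes without a domain: {sorted(missing)}")

    # integer-code everything once; recursion then runs on numpy arrays
    classes = sorted(set(df[class_column]))  # sorted -> first-max tie-break
    n_cls = len(classes)
    y = np.searchsorted(classes, df[class_column].to_numpy())
    codes: list[np.ndarray] = []
    for a in attrs:
        dom = list(domains[a])
        lut = {lab: i for i, lab in enumerate(dom)}
        col = df[a].to_numpy()
        try:
            codes.append(np.array([lut[v] for v in col]))
        except KeyError as exc:
            raise KeyError(
                f"label {exc.args[0]!r} of attribute {a!r} is not in its "
                "domain") from exc

    def entropy_of(counts: np.ndarray) -> float:
        n = counts.sum()
        p = counts[counts > 0] / n
        return float(-(p * np.log2(p)).sum())

    def grow(rows: np.ndarray, remaining: list[int]) -> DecisionNode:
        ysub = y[rows]
        ycounts = np.bincount(ysub, minlength=n_cls)
        maj_idx = int(np.argmax(ycounts))
        majority = classes[maj_idx]
        counts = {classes[i]: int(c) for i, c in enumerate(ycounts) if c > 0}
        if len(counts) == 1 or not remaining or len(rows) < min_support:
            return DecisionNode(
                kind="leaf", majority_class=majority, support=len(rows),
                predicted_class=majority, class_counts=counts)
        parent = entropy_of(ycounts)
        best_gain, best = -1.0, -1
        n = len(rows)
        for ai in remaining:
            c = codes[ai][rows]
            n_lab = len(domains[attrs[ai]])
            joint = np.bincount(
                c * n_cls + ysub, minlength=n_lab * n_cls
            ).reshape(n_lab, n_cls)
            sizes = joint.sum(axis=1)
            child = 0.0
            for v in range(n_lab):
                if sizes[v]:
                    child += sizes[v] / n * entropy_of(joint[v])
            gain = parent - child
            if gain > best_gain:  # strict: column-order tie-break (first wins)
                best_gain, best = gain, ai
        attr = attrs[best]
        rest = [ai for ai in remaining if ai != best]
        c = codes[best][rows]
        branches: dict[str, DecisionNode] = {}
        for v, label in enumerate(domains[attr]):
            sub_rows = rows[c == v]
            if len(sub_rows) == 0:
                branches[label] = DecisionNode(
                    kind="leaf", majority_class=majority, support=0,
                    predicted_class=majority, class_counts={})
            else:
                branches[label] = grow(sub_rows, rest)
        return DecisionNode(
            kind="internal", majority_class=majority, support=len(rows),
            attribute=attr, branches=branches)

    return grow(np.arange(len(df)), list(range(len(attrs))))


@dataclass(frozen=True)
class FuzzyRule:
    """An IF-THEN rule extracted from one root-to-leaf path.

    ``confidence`` is the leaf's purity — the fraction of covered training
    rows whose class equals the consequent; it is used only for tie-breaking
    in soft inference.
    """

    antecedents: tuple[tuple[str, str], ...]  # (attribute, label) in path order
    consequent: str
    support: int
    confidence: float

    def format(self) -> str:
        if not self.antecedents:
            return f"THEN CLASS IS {self.consequent}"
        cond = " AND ".join(f"({attr} IS {lab})" for attr, lab in self.antecedents)
        return f"IF {cond} THEN CLASS IS {self.consequent}"

    def to_dict(self) -> dict:
        return {
            "antecedents": [list(p) for p in self.antecedents],
            "consequent": self.consequent,
            "support": self.support,
            "confidence": self.confidence,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzyRule":
        return cls(
            antecedents=tuple((a, l) for a, l in d["antecedents"]),
            consequent=d["consequent"],
            support=int(d["support"]),
            confidence=float(d["confidence"]),
        )


def extract_rules(tree: DecisionNode) -> list[FuzzyRule]:
    """One rule per leaf, antecedents in root-to-leaf path order.

    The rules partition the linguistic input space: every complete label
    assignment matches exactly one rule (branch completeness guarantees it).
    Empty leaves yield support-0 rules with confidence 0.
    """
    rules: list[FuzzyRule] = []

    def walk(node: DecisionNode, path: tuple[tuple[str, str], ...]) -> None:
        if node.is_leaf:
            correct = node.class_counts.get(node.predicted_class, 0)
            conf = correct / node.support if node.support else 0.0
            rules.append(FuzzyRule(path, node.predicted_class, node.support, conf))
            return
        for label, child in node.branches.items():
            walk(child, path + ((node.attribute, label),))

    walk(tree, ())
    return rules


def rules_to_json(rules: Sequence[FuzzyRule], path=None) -> str | None:
    text = json.dumps([r.to_dict() for r in rules], indent=2)
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)
    return None


def rules_from_json(path) -> list[FuzzyRule]:
    with open(path) as fh:
        return [FuzzyRule.from_dict(d) for d in json.load(fh)]
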