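"""Convenience estimator tying the pipeline together.

``FuzzyID3Classifier`` follows the familiar fit/predict shape: fitting builds
the fuzzy database on the training table, fuzzifies it, induces the ID3 tree
and extracts the rule base; prediction runs either crisp traversal on
fuzzified inputs or soft highest-compatibility-rule matching on raw inputs.
The fitted model round-trips through a single JSON document (database + tree
+ rules), which is what the command-line ``train``/``predict`` commands
exchange.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Mapping

import pandas as pd

from .fuzzify import LinguisticTable, assign_label, fuzzify_table
from .inference import (Prediction, classify_crisp, classify_soft,
                        predict_crisp_table)
from .membership import FuzzyDatabase, build_fuzzy_database
from .tree import (DecisionNode, FuzzyRule, extract_rules, induce_tree)


@dataclass
class FuzzyID3Classifier:
    k_default: int = 3
    k_overrides: dict[str, int] = field(default_factory=dict)
    tie_break: str = "left"
    tnorm: Literal["min", "product"] = "min"
    min_support: int = 1

    db: FuzzyDatabase | None = None
    tree: DecisionNode | None = None
    rules: list[FuzzyRule] | None = None
    classes_: tuple[str, ...] | None = None
    majority_class_: str | None = None

    def fit(self, raw: pd.DataFrame, class_column: str = "class") -> "FuzzyID3Classifier":
        self.db = build_fuzzy_database(
            raw, self.k_default, self.k_overrides, class_column)
        ling = fuzzify_table(raw, self.db, class_column, self.tie_break)
        if len(ling.classes) < 2:
            import warnings

            warnings.warn("training table has a single class; the tree is a "
                          "single leaf", stacklevel=2)
        self.tree = induce_tree(ling, self.db, self.min_support)
        self.rules = extract_rules(self.tree)
        counts = Counter(ling.class_labels())
        best = max(counts.values())
        self.majority_class_ = min(c for c, n in counts.items() if n == best)
        self.classes_ = ling.classes
        return self

    def _check_fitted(self) -> None:
        if self.tree is None:
            raise RuntimeError("classifier is not fitted")

    def fuzzify(self, raw: pd.DataFrame, class_column: str = "class") -> LinguisticTable:
        self._check_fitted()
        return fuzzify_table(raw, self.db, class_column, self.tie_break)

    def predict(
        self,
        raw: pd.DataFrame,
        mode: Literal["crisp", "soft"] = "crisp",
        class_column: str = "class",
    ) -> list[str]:
        """Crisp mode fuzzifies the rows and traverses the tree; soft mode
        scores the rule base by compatibility degree on the raw values."""
        self._check_fitted()
        if mode == "crisp":
            cols = {a: raw[a] for a in self.db.attributes}
            if class_column in raw.columns:
                cols[class_column] = raw[class_column]
            else:
                cols[class_column] = ["?"] * len(raw)
            ling = fuzzify_table(
                pd.DataFrame(cols), self.db, class_column, self.tie_break)
            return list(predict_crisp_table(self.tree, ling.df))
        return [p.predicted_class for p in self.predict_detailed(raw)]

    def predict_detailed(self, raw: pd.DataFrame) -> list[Prediction]:
        """Soft predictions carrying the matched rule and its compatibility."""
        self._check_fitted()
        out = []
        for _, row in raw.iterrows():
            instance = {a: float(row[a]) for a in self.db.attributes}
            out.append(classify_soft(
                self.rules, instance, self.db, self.tnorm,
                default_class=self.majority_class_))
        return out

    def predict_one(self, instance: Mapping, mode: str = "crisp") -> Prediction:
        self._check_fitted()
        if mode == "crisp":
            labels = {
                a: instance[a] if isinstance(instance[a], str)
                else assign_label(self.db[a], float(instance[a]), self.tie_break)
                for a in self.db.attributes
            }
            return classify_crisp(self.tree, labels)
        return classify_soft(
            self.rules, {a: float(instance[a]) for a in self.db.attributes},
            self.db, self.tnorm, default_class=self.majority_class_)

    # persistence ----------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "fuzzy_database": self.db.to_dict(),
            "tree": self.tree.to_dict(),
            "rules": [r.to_dict() for r in self.rules],
            "classes": list(self.classes_),
            "majority_class": self.majority_class_,
            "config": {
                "k_default": self.k_default,
                "k_overrides": dict(self.k_overrides),
                "tie_break": self.tie_break,
                "tnorm": self.tnorm,
                "min_support": self.min_support,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzyID3Classifier":
        cfg = d.get("config", {})
        model = cls(
            k_default=int(cfg.get("k_default", 3)),
            k_overrides=dict(cfg.get("k_overrides", {})),
            tie_break=cfg.get("tie_break", "left"),
            tnorm=cfg.get("tnorm", "min"),
            min_support=int(cfg.get("min_support", 1)),
        )
        model.db = FuzzyDatabase.from_dict(d["fuzzy_database"])
        model.tree = DecisionNode.from_dict(d["tree"])
        model.rules = [FuzzyRule.from_dict(r) for r in d["rules"]]
        model.classes_ = tuple(d["classes"])
        model.majority_class_ = d["majority_class"]
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "FuzzyID3Classifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
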