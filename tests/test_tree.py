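"""ID3 induction: entropy, information gain, tree growth, rule extraction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fuzzyid3 import (
    DecisionNode,
    LinguisticTable,
    class_entropy,
    classify_crisp,
    extract_rules,
    induce_tree,
    information_gain,
)
from fuzzyid3.tree import rules_from_json, rules_to_json

from conftest import oracle_entropy, oracle_gain, random_linguistic_table


class TestEntropy:
    def test_uniform_two_class_is_one_bit(self):
        assert class_entropy({"A": 7, "B": 7}) == pytest.approx(1.0, abs=1e-15)

    def test_pure_is_zero(self):
        assert class_entropy({"A": 12}) == 0.0

    def test_nine_five_split(self):
        # independent evaluation of -(9/14)log2(9/14) - (5/14)log2(5/14)
        assert class_entropy({"A": 9, "B": 5}) == pytest.approx(
            oracle_entropy({"A": 9, "B": 5}), abs=1e-15)
        assert class_entropy({"A": 9, "B": 5}) == pytest.approx(0.94029, abs=5e-6)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            class_entropy({})

    def test_bounded_by_log_classes(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = int(rng.integers(2, 6))
            counts = {f"c{i}": int(rng.integers(1, 30)) for i in range(k)}
            e = class_entropy(counts)
            assert 0.0 <= e <= np.log2(k) + 1e-12


class TestInformationGain:
    def test_constant_attribute_zero_gain(self, weather_table):
        df = weather_table.df.copy()
        df["const"] = "same"
        t = LinguisticTable(df, weather_table.attributes + ("const",))
        assert information_gain(t, "const") == pytest.approx(0.0, abs=1e-15)

    def test_perfect_predictor_gain_equals_entropy(self, weather_table):
        df = weather_table.df.copy()
        df["oracle"] = df["class"].map({"yes": "Y", "no": "N"})
        t = LinguisticTable(df, weather_table.attributes + ("oracle",))
        parent = class_entropy(dict(df["class"].value_counts()))
        assert information_gain(t, "oracle") == pytest.approx(parent, abs=1e-12)

    def test_weather_outlook_gain(self, weather_table):
        gain = information_gain(weather_table, "outlook")
        assert gain == pytest.approx(oracle_gain(weather_table.df, "outlook"),
                                     abs=1e-12)
        assert gain == pytest.approx(0.2467, abs=5e-5)

    def test_unknown_attribute_is_error(self, weather_table):
        with pytest.raises(KeyError):
            information_gain(weather_table, "nonexistent")

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            table, _ = random_linguistic_table(rng)
            for attr in table.attributes:
                assert information_gain(table, attr) == pytest.approx(
                    oracle_gain(table.df, attr), abs=1e-12)

    def test_gain_nonnegative_and_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            table, _ = random_linguistic_table(rng)
            parent = class_entropy(dict(table.df["class"].value_counts()))
            for attr in table.attributes:
                g = information_gain(table, attr)
                assert -1e-12 <= g <= parent + 1e-12


class TestInduceTree:
    def test_pure_table_single_leaf(self):
        df = pd.DataFrame({"a0": ["L0", "L1"], "class": ["c", "c"]})
        t = LinguisticTable(df, ("a0",))
        tree = induce_tree(t, {"a0": ("L0", "L1", "L2")})
        assert tree.is_leaf and tree.predicted_class == "c"

    def test_empty_table_is_error(self):
        df = pd.DataFrame({"a0": [], "class": []})
        with pytest.raises(ValueError):
            induce_tree(LinguisticTable(df, ("a0",)), {"a0": ("L0",)})

    def test_root_is_argmax_gain_attribute(self, weather_table, weather_domains):
        gains = {a: oracle_gain(weather_table.df, a)
                 for a in weather_table.attributes}
        best = max(gains, key=gains.get)
        tree = induce_tree(weather_table, weather_domains)
        assert tree.attribute == best == "outlook"

    def test_resubstitution_perfect_on_consistent_data(self, weather_table,
                                                       weather_domains):
        tree = induce_tree(weather_table, weather_domains)
        for row in weather_table.iter_rows():
            assert classify_crisp(tree, row).predicted_class == row["class"]

    def test_noise_free_function_recovered(self):
        # class is a deterministic function of the labels; tree must represent it
        labels = ("L0", "L1", "L2")
        rng = np.random.default_rng(5)
        assignments = list(itertools.product(labels, repeat=3))
        fn = {cell: f"c{rng.integers(0, 2)}" for cell in assignments}
        rows = [dict(zip(("a0", "a1", "a2"), cell), **{"class": fn[cell]})
                for cell in assignments for _ in range(2)]
        t = LinguisticTable(pd.DataFrame(rows), ("a0", "a1", "a2"))
        domains = {a: labels for a in ("a0", "a1", "a2")}
        tree = induce_tree(t, domains)
        for cell in assignments:
            pred = classify_crisp(tree, dict(zip(("a0", "a1", "a2"), cell)))
            assert pred.predicted_class == fn[cell]

    def test_branch_completeness_over_domain(self, weather_table, weather_domains):
        tree = induce_tree(weather_table, weather_domains)

        def walk(node):
            if node.is_leaf:
                return
            assert set(node.branches) == set(weather_domains[node.attribute])
            for child in node.branches.values():
                walk(child)

        walk(tree)

    def test_no_attribute_repeats_on_a_path(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            table, domains = random_linguistic_table(rng, n_rows=30, n_attrs=4)
            tree = induce_tree(table, domains)
            assert tree.depth() <= len(table.attributes)

            def walk(node, seen):
                if node.is_leaf:
                    return
                assert node.attribute not in seen
                for child in node.branches.values():
                    walk(child, seen | {node.attribute})

            walk(tree, set())

    def test_single_class_gives_single_leaf(self):
        df = pd.DataFrame({"a0": ["L0", "L1", "L2"], "class": ["c"] * 3})
        tree = induce_tree(
            LinguisticTable(df, ("a0",)), {"a0": ("L0", "L1", "L2")})
        assert tree.is_leaf

    def test_deterministic_structure(self):
        rng = np.random.default_rng(13)
        table, domains = random_linguistic_table(rng, n_rows=40, n_attrs=3)
        t1 = induce_tree(table, domains)
        t2 = induce_tree(table, domains)
        assert t1.to_dict() == t2.to_dict()

    def test_leaf_class_tie_broken_lexicographically(self):
        df = pd.DataFrame({"a0": ["L0", "L0"], "class": ["zebra", "ant"]})
        tree = induce_tree(LinguisticTable(df, ("a0",)), {"a0": ("L0",)})
        leaf = next(tree.iter_leaves())
        assert leaf.predicted_class == "ant"


class TestExtractRules:
    def test_depth_one_tree_k3_gives_three_rules(self):
        df = pd.DataFrame({"a0": ["L0", "L1", "L2"],
                           "class": ["x", "y", "x"]})
        tree = induce_tree(
            LinguisticTable(df, ("a0",)), {"a0": ("L0", "L1", "L2")})
        rules = extract_rules(tree)
        assert len(rules) == 3 == tree.n_leaves()

    def test_single_leaf_tree_gives_empty_antecedent_rule(self):
        df = pd.DataFrame({"a0": ["L0"], "class": ["c"]})
        tree = induce_tree(LinguisticTable(df, ("a0",)), {"a0": ("L0",)})
        rules = extract_rules(tree)
        assert len(rules) == 1
        assert rules[0].antecedents == ()
        assert rules[0].consequent == "c"

    def test_rules_reproduce_traversal_exhaustively(self):
        labels = ("L0", "L1", "L2")
        rng = np.random.default_rng(17)
        for n_attrs in (1, 2, 3, 4):
            table, domains = random_linguistic_table(
                rng, n_rows=50, n_attrs=n_attrs)
            tree = induce_tree(table, domains)
            rules = extract_rules(tree)
            for combo in itertools.product(labels, repeat=n_attrs):
                instance = dict(zip(table.attributes, combo))
                matches = [r for r in rules
                           if all(instance[a] == lab for a, lab in r.antecedents)]
                assert len(matches) == 1  # rules partition the label space
                assert (matches[0].consequent
                        == classify_crisp(tree, instance).predicted_class)

    def test_rule_confidence_is_leaf_purity(self, weather_table, weather_domains):
        tree = induce_tree(weather_table, weather_domains)
        for rule in extract_rules(tree):
            assert 0.0 <= rule.confidence <= 1.0
            if rule.support > 0:
                covered = weather_table.df
                for attr, lab in rule.antecedents:
                    covered = covered[covered[attr] == lab]
                assert len(covered) == rule.support
                frac = (covered["class"] == rule.consequent).mean()
                assert rule.confidence == pytest.approx(frac)

    def test_rule_format_uses_if_is_then_form(self, weather_table, weather_domains):
        tree = induce_tree(weather_table, weather_domains)
        text = extract_rules(tree)[0].format()
        assert text.startswith("IF (") and " IS " in text and "THEN CLASS IS" in text


class TestTreeSerialization:
    def test_tree_json_round_trip(self, weather_table, weather_domains, tmp_path):
        tree = induce_tree(weather_table, weather_domains)
        path = tmp_path / "tree.json"
        tree.to_json(path)
        import json

        back = DecisionNode.from_dict(json.load(open(path)))
        for row in weather_table.iter_rows():
            assert (classify_crisp(back, row).predicted_class
                    == classify_crisp(tree, row).predicted_class)

    def test_rules_json_round_trip(self, weather_table, weather_domains, tmp_path):
        rules = extract_rules(induce_tree(weather_table, weather_domains))
        path = tmp_path / "rules.json"
        rules_to_json(rules, path)
        assert rules_from_json(path) == rules
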