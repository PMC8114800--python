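"""Planted-rule synthetic data with the structure the fuzzy pipeline assumes.

Each attribute carries an equalized-universe triangular partition; a class is
drawn per row, then a label cell compatible with that class, and each
attribute value is a Gaussian draw centred at its label's fuzzy-set peak and
clamped to the universe.  The class is a deterministic decision-list function
of the label cell, so at ``noise_sd = 0`` fuzzification recovers the drawn
labels — and hence the classes — exactly.

The defaults are the recovery-experiment conditions used throughout the test
suite: 4 attributes, 3 fuzzy sets each, 500 rows, two classes, and Gaussian
noise with standard deviation equal to a tenth of the peak spacing.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .membership import build_partition, default_labels

Rule = tuple[Mapping[str, str], str]  # ({attribute: label, ...}, class)

UNIVERSE = (0.0, 10.0)


def default_planted_rules(
    n_attributes: int, k: int, n_classes: int = 2
) -> tuple[list[Rule], str]:
    """A decision list over the first two attributes, plus a default class.

    Keeping the rules on a two-attribute subspace makes the target concept a
    function of few attributes, which an unpruned tree can represent exactly
    and generalise from — the regime the planted-rule recovery experiments
    probe.
    """
    labels = default_labels(k)
    classes = class_names(n_classes)
    a1 = "attr1"
    a2 = "attr2" if n_attributes >= 2 else "attr1"
    second = classes[1] if n_classes > 2 else classes[0]
    rules: list[Rule] = [
        ({a1: labels[0]}, classes[0]),
        ({a2: labels[-1]}, second),
    ]
    default = classes[-1]
    return rules, default


def class_names(n_classes: int) -> tuple[str, ...]:
    if n_classes == 2:
        return ("case", "control")
    return tuple(f"class{i + 1}" for i in range(n_classes))


@dataclass
class SyntheticSpec:
    """Generator configuration; ``planted_rules=None`` means the default
    two-attribute decision list."""

    n_attributes: int = 4
    k: int = 3
    n_rows: int = 500
    n_classes: int = 2
    planted_rules: list[Rule] | None = None
    default_class: str | None = None
    noise_sd: float | None = None  # None -> 0.1 * peak spacing
    class_balance: Sequence[float] | None = None
    seed: int = 0
    universe: tuple[float, float] = UNIVERSE

    def __post_init__(self) -> None:
        if self.planted_rules is None:
            self.planted_rules, default = default_planted_rules(
                self.n_attributes, self.k, self.n_classes)
            if self.default_class is None:
                self.default_class = default
        if self.noise_sd is None:
            lo, hi = self.universe
            self.noise_sd = 0.1 * (hi - lo) / (self.k - 1)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(f"attr{i + 1}" for i in range(self.n_attributes))

    @property
    def labels(self) -> tuple[str, ...]:
        return default_labels(self.k)


def _check_rules(spec: SyntheticSpec) -> None:
    seen: dict[tuple, str] = {}
    valid = set(spec.labels)
    for conds, cls in spec.planted_rules:
        unknown = set(conds) - set(spec.attributes)
        if unknown:
            raise ValueError(f"rule names unknown attributes: {sorted(unknown)}")
        bad = {v for v in conds.values()} - valid
        if bad:
            raise ValueError(f"rule uses unknown labels: {sorted(bad)}")
        key = tuple(sorted(conds.items()))
        if key in seen and seen[key] != cls:
            raise ValueError(
                f"contradictory rules: antecedents {dict(conds)} map to both "
                f"{seen[key]!r} and {cls!r}")
        seen[key] = cls


def resolve_cell(
    cell: Mapping[str, str],
    rules: Sequence[Rule],
    default_class: str | None,
) -> str:
    """Class of a full label assignment under first-match decision-list
    semantics, falling back to the default class."""
    for conds, cls in rules:
        if all(cell[a] == lab for a, lab in conds.items()):
            return cls
    if default_class is None:
        raise ValueError(f"no rule covers the label cell {dict(cell)}")
    return default_class


def label_grid(spec: SyntheticSpec) -> list[dict[str, str]]:
    """Every complete label assignment over the spec's attributes."""
    return [
        dict(zip(spec.attributes, combo))
        for combo in itertools.product(spec.labels, repeat=spec.n_attributes)
    ]


def generate_synthetic(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a raw numeric table plus its ground truth.

    Returns ``(table, truth)`` where ``truth`` records the planted rules,
    default class, drawn label grid and per-attribute peaks.  Reproducible
    from ``spec.seed``.
    """
    _check_rules(spec)
    rng = np.random.default_rng(spec.seed)
    classes = class_names(spec.n_classes)

    grid = label_grid(spec)
    cell_class = [resolve_cell(cell, spec.planted_rules, spec.default_class)
                  for cell in grid]
    by_class: dict[str, list[int]] = {c: [] for c in classes}
    for i, cls in enumerate(cell_class):
        if cls not in by_class:
            raise ValueError(f"rule class {cls!r} not among {classes}")
        by_class[cls].append(i)
    reachable = [c for c in classes if by_class[c]]
    if spec.class_balance is None:
        balance = np.full(len(reachable), 1.0 / len(reachable))
    else:
        balance = np.asarray(spec.class_balance, dtype=float)
        if len(balance) != len(classes):
            raise ValueError("class_balance length must equal n_classes")
        balance = balance[[classes.index(c) for c in reachable]]
        balance = balance / balance.sum()

    lo, hi = spec.universe
    part = build_partition("attr", lo, hi, spec.k, labels=spec.labels)
    peak_of = dict(zip(part.labels, part.peaks))

    drawn_classes = rng.choice(reachable, size=spec.n_rows, p=balance)
    rows = np.empty((spec.n_rows, spec.n_attributes))
    drawn_cells: list[dict[str, str]] = []
    for r, cls in enumerate(drawn_classes):
        cell = grid[by_class[cls][rng.integers(len(by_class[cls]))]]
        drawn_cells.append(cell)
        for j, attr in enumerate(spec.attributes):
            val = peak_of[cell[attr]] + rng.normal(0.0, spec.noise_sd)
            rows[r, j] = min(max(val, lo), hi)

    table = pd.DataFrame(rows, columns=list(spec.attributes))
    table["class"] = drawn_classes
    truth = {
        "planted_rules": [[dict(c), cls] for c, cls in spec.planted_rules],
        "default_class": spec.default_class,
        "attributes": list(spec.attributes),
        "labels": list(spec.labels),
        "peaks": {lab: peak_of[lab] for lab in spec.labels},
        "universe": list(spec.universe),
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "drawn_cells": drawn_cells,
    }
    return table, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)


# ---------------------------------------------------------------------------
# synthetic stand-in for the 699-row UCI-dialect file (no download required)

def write_wbcd_like(path, seed: int = 0) -> None:
    """Write a *synthetic* delimited file mimicking the WBCD dialect.

    Layout: id column, nine integer attributes in 1..10, class coded 2/4;
    699 rows of which exactly 16 contain the missing marker "?" in the
    bare-nuclei column, and a 458/241 benign/malignant split — so listwise
    deletion leaves 683 rows.  The attribute values are class-conditional
    (malignant shifted high), not real patient data.
    """
    rng = np.random.default_rng(seed)
    n_benign, n_malig = 458, 241
    n = n_benign + n_malig
    y = np.array([2] * n_benign + [4] * n_malig)
    rng.shuffle(y)
    means = np.where(y == 2, 3.0, 7.0)
    cols = []
    for _ in range(9):
        vals = np.clip(np.round(rng.normal(means, 2.0)), 1, 10).astype(int)
        cols.append(vals)
    data = np.column_stack(cols)
    missing_rows = rng.choice(n, size=16, replace=False)
    ids = 1000000 + rng.choice(9000000, size=n, replace=False)
    with open(path, "w") as fh:
        for r in range(n):
            cells = [str(ids[r])]
            for j in range(9):
                if j == 5 and r in missing_rows:
                    cells.append("?")
                else:
                    cells.append(str(data[r, j]))
            cells.append(str(y[r]))
            fh.write(",".join(cells) + "\n")
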