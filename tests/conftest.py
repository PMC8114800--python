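"""Shared fixtures and independent brute-force oracles.

The oracle functions implement entropy/information gain/metrics directly from
their defining formulas using only the standard library and math — no code is
shared with the package modules they check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from fuzzyid3 import LinguisticTable, build_partition


# ---------------------------------------------------------------------------
# oracles (kept independent of fuzzyid3 internals)

def oracle_entropy(counts) -> float:
    values = list(counts.values()) if isinstance(counts, dict) else list(counts)
    n = sum(values)
    e = 0.0
    for c in values:
        if c > 0:
            p = c / n
            e -= p * math.log2(p)
    return e


def oracle_gain(df: pd.DataFrame, attribute: str, class_column: str = "class") -> float:
    n = len(df)
    parent = oracle_entropy(Counter(df[class_column]))
    child = 0.0
    for v in df[attribute].unique():
        sub = df[df[attribute] == v]
        child += len(sub) / n * oracle_entropy(Counter(sub[class_column]))
    return parent - child


def oracle_triangle(a: float, b: float, c: float, x: float) -> float:
    if x == b:
        return 1.0
    if a <= x < b:
        return (x - a) / (b - a) if b > a else 0.0
    if b < x <= c:
        return (c - x) / (c - b) if c > b else 0.0
    return 0.0


def oracle_paired_t(a, b) -> tuple[float, int]:
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    return mean / math.sqrt(var / n), n - 1


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def partition3():
    """k=3 partition over [0, 10]: low=(0,0,5), medium=(0,5,10), high=(5,10,10)."""
    return build_partition("x", 0.0, 10.0, 3)


WEATHER_ROWS = [
    # (outlook, temperature, humidity, wind, play)
    ("sunny", "hot", "high", "weak", "no"),
    ("sunny", "hot", "high", "strong", "no"),
    ("overcast", "hot", "high", "weak", "yes"),
    ("rain", "mild", "high", "weak", "yes"),
    ("rain", "cool", "normal", "weak", "yes"),
    ("rain", "cool", "normal", "strong", "no"),
    ("overcast", "cool", "normal", "strong", "yes"),
    ("sunny", "mild", "high", "weak", "no"),
    ("sunny", "cool", "normal", "weak", "yes"),
    ("rain", "mild", "normal", "weak", "yes"),
    ("sunny", "mild", "normal", "strong", "yes"),
    ("overcast", "mild", "high", "strong", "yes"),
    ("overcast", "hot", "normal", "weak", "yes"),
    ("rain", "mild", "high", "strong", "no"),
]

WEATHER_DOMAINS = {
    "outlook": ("sunny", "overcast", "rain"),
    "temperature": ("hot", "mild", "cool"),
    "humidity": ("high", "normal"),
    "wind": ("weak", "strong"),
}


@pytest.fixture
def weather_table() -> LinguisticTable:
    """The classic 14-row categorical weather table (9 yes / 5 no)."""
    df = pd.DataFrame(
        WEATHER_ROWS,
        columns=["outlook", "temperature", "humidity", "wind", "class"],
    )
    return LinguisticTable(df, ("outlook", "temperature", "humidity", "wind"))


@pytest.fixture
def weather_domains():
    return dict(WEATHER_DOMAINS)


def random_linguistic_table(
    rng: np.random.Generator,
    n_rows: int | None = None,
    n_attrs: int | None = None,
    k: int = 3,
    n_classes: int = 2,
) -> tuple[LinguisticTable, dict[str, tuple[str, ...]]]:
    """A random small linguistic table plus its attribute domains."""
    if n_rows is None:
        n_rows = int(rng.integers(2, 40))
    if n_attrs is None:
        n_attrs = int(rng.integers(1, 5))
    labels = tuple(f"L{i}" for i in range(k))
    classes = [f"c{i}" for i in range(n_classes)]
    data = {
        f"a{j}": rng.choice(labels, size=n_rows) for j in range(n_attrs)
    }
    data["class"] = rng.choice(classes, size=n_rows)
    df = pd.DataFrame(data)
    domains = {f"a{j}": labels for j in range(n_attrs)}
    return LinguisticTable(df, tuple(domains)), domains
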