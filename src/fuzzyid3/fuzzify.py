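"""Fuzzification: raw numeric values -> membership vectors -> linguistic labels.

Each cell of a raw table is replaced by the label of its highest-membership
fuzzy set; the class column is copied verbatim.  At an exact 0.5 crossing the
two adjacent sets tie, and the assignment is standardised (left label by
default) rather than random, to keep the pipeline reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .membership import FuzzyDatabase, FuzzyPartition, membership_degree

TieBreak = Literal["left", "right"]


@dataclass(frozen=True)
class MembershipVector:
    """An input value's degrees across one attribute's fuzzy sets (aligned
    with the partition's label order; sums to 1 for in-universe values)."""

    attribute: str
    degrees: tuple[tuple[str, float], ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.degrees)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(d for _, d in self.degrees)

    def argmax_label(self, tie_break: TieBreak = "left") -> str:
        vals = self.values
        best = max(vals)
        idx = vals.index(best) if tie_break == "left" else (
            len(vals) - 1 - vals[::-1].index(best))
        return self.degrees[idx][0]


def fuzzify_value(partition: FuzzyPartition, x: float) -> MembershipVector:
    """Membership degrees of ``x`` across the partition's sets.

    ``x`` is clamped to the universe first, so the degrees always sum to 1
    and at most two (adjacent) entries are nonzero.
    """
    if not math.isfinite(x):
        raise ValueError(
            f"non-finite value {x!r} for attribute {partition.attribute!r}")
    xc = partition.clamp(x)
    return MembershipVector(
        partition.attribute,
        tuple((mf.label, membership_degree(mf, xc)) for mf in partition.mfs),
    )


def assign_label(
    partition: FuzzyPartition, x: float, tie_break: TieBreak = "left"
) -> str:
    """Label of the highest-membership set for ``x`` (ties standardised)."""
    return fuzzify_value(partition, x).argmax_label(tie_break)


@dataclass
class LinguisticTable:
    """A fuzzified dataset: label strings per predictive attribute plus the
    untouched class column.  Backed by a pandas DataFrame."""

    df: pd.DataFrame
    attributes: tuple[str, ...]
    class_column: str = "class"

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(self.df[self.class_column].unique()))

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def class_labels(self) -> pd.Series:
        return self.df[self.class_column]

    def iter_rows(self) -> Iterator[dict[str, str]]:
        for row in self.df.itertuples(index=False):
            yield dict(zip(self.df.columns, row))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, class_column: str = "class") -> "LinguisticTable":
        df = pd.read_csv(path, dtype=str)
        attrs = tuple(c for c in df.columns if c != class_column)
        return cls(df, attrs, class_column)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LinguisticTable)
            and self.attributes == other.attributes
            and self.class_column == other.class_column
            and self.df.reset_index(drop=True).equals(
                other.df.reset_index(drop=True))
        )


def fuzzify_table(
    table: pd.DataFrame,
    db: FuzzyDatabase,
    class_column: str = "class",
    tie_break: TieBreak = "left",
) -> LinguisticTable:
    """Replace every predictive cell with its argmax linguistic label.

    Attribute and row order are preserved; attributes the database excluded
    (constants) are dropped; any other attribute missing from the database is
    an error.  Vectorised over rows: the argmax label of a value in an
    equalized-universe partition is a function of which inter-peak band the
    value falls in.
    """
    predictive = [c for c in table.columns if c != class_column]
    missing = [c for c in predictive
               if c not in db and c not in db.excluded]
    if missing:
        raise KeyError(f"attributes missing from the fuzzy database: {missing}")

    out = {}
    for name in predictive:
        if name in db.excluded:
            continue
        part = db[name]
        x = pd.to_numeric(table[name], errors="raise").to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            bad = int(np.flatnonzero(~np.isfinite(x))[0])
            raise ValueError(
                f"non-finite value in attribute {name!r} at row {bad}")
        xc = np.clip(x, part.universe_min, part.universe_max)
        # band edges are the 0.5-crossing midpoints between adjacent peaks
        peaks = np.asarray(part.peaks)
        edges = (peaks[:-1] + peaks[1:]) / 2.0
        if tie_break == "left":
            idx = np.searchsorted(edges, xc, side="left")
        else:
            idx = np.searchsorted(edges, xc, side="right")
        labels = np.asarray(part.labels, dtype=object)
        out[name] = labels[idx]
    out[class_column] = table[class_column].astype(str).to_numpy()

    cols = [c for c in table.columns
            if c == class_column or (c in db and c not in db.excluded)]
    df = pd.DataFrame(out, index=table.index)[cols]
    attrs = tuple(c for c in cols if c != class_column)
    return LinguisticTable(df.reset_index(drop=True), attrs, class_column)
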