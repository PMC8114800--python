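"""Automatic fuzzy-database definition: equalized-universe triangular partitions.

Every attribute gets ``k`` triangular membership functions whose peaks are
equally spaced over the attribute's observed range, with the observed minimum
and maximum sitting at the outermost peaks.  Adjacent triangles half-overlap,
so memberships form a partition of unity and cross at exactly 0.5 midway
between peaks — no point of the universe has two memberships above 0.5.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

K_MIN, K_MAX = 2, 10

#: default linguistic label schemes, overridable per call / via config
DEFAULT_LABELS: dict[int, tuple[str, ...]] = {
    2: ("low", "high"),
    3: ("low", "medium", "high"),
    5: ("verylow", "low", "medium", "high", "veryhigh"),
    7: (
        "extremelylow",
        "verylow",
        "low",
        "medium",
        "high",
        "veryhigh",
        "extremelyhigh",
    ),
}


class DegenerateUniverseError(ValueError):
    """Raised when an attribute's observed range collapses to a point."""


def default_labels(k: int) -> tuple[str, ...]:
    """Linguistic labels for a ``k``-set partition (generic ``set1..setk``
    when no named scheme exists)."""
    if k in DEFAULT_LABELS:
        return DEFAULT_LABELS[k]
    return tuple(f"set{i + 1}" for i in range(k))


@dataclass(frozen=True)
class TriangularMF:
    """A triangular membership function with feet ``a``/``c`` and peak ``b``.

    Outermost sets in a partition are shoulder triangles (``a == b`` or
    ``b == c``) so that the partition of unity holds on the closed universe.
    """

    label: str
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c):
            raise ValueError(f"invalid breakpoints for {self.label!r}: "
                             f"need a <= b <= c, got ({self.a}, {self.b}, {self.c})")

    def __call__(self, x: float) -> float:
        return membership_degree(self, x)


def membership_degree(mf: TriangularMF, x: float) -> float:
    """Degree of membership of ``x`` in ``mf``: piecewise-linear triangle.

    1 exactly at the peak, 0 at and beyond the feet; shoulder cases
    (``a == b`` / ``b == c``) evaluate without division by zero.
    """
    x = float(x)
    if x != x or x in (float("inf"), float("-inf")):
        raise ValueError(f"non-finite value {x!r} for attribute set {mf.label!r}")
    if x == mf.b:
        return 1.0
    if x < mf.b:
        if x <= mf.a:  # covers the left shoulder a == b
            return 0.0
        return (x - mf.a) / (mf.b - mf.a)
    if x >= mf.c:  # covers the right shoulder b == c
        return 0.0
    return (mf.c - x) / (mf.c - mf.b)


@dataclass(frozen=True)
class FuzzyPartition:
    """One attribute's fuzzy sets: ``k`` half-overlapping triangles whose
    peaks are equally spaced over ``[universe_min, universe_max]``."""

    attribute: str
    universe_min: float
    universe_max: float
    k: int
    mfs: tuple[TriangularMF, ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(mf.label for mf in self.mfs)

    @property
    def peaks(self) -> tuple[float, ...]:
        return tuple(mf.b for mf in self.mfs)

    @property
    def peak_spacing(self) -> float:
        return (self.universe_max - self.universe_min) / (self.k - 1)

    def clamp(self, x: float) -> float:
        return min(max(float(x), self.universe_min), self.universe_max)


def build_partition(
    attribute: str,
    universe_min: float,
    universe_max: float,
    k: int,
    labels: Sequence[str] | None = None,
) -> FuzzyPartition:
    """Build the equalized-universe partition for one attribute.

    Peaks are ``b_i = min + i * (max - min) / (k - 1)`` (computed from the
    closed formula, never by repeated addition, so breakpoints are
    bit-reproducible); interior set *i* spans ``(b_{i-1}, b_i, b_{i+1})`` and
    the outer sets are shoulders anchored at the universe bounds.
    """
    universe_min = float(universe_min)
    universe_max = float(universe_max)
    if not universe_min < universe_max:
        raise DegenerateUniverseError(
            f"attribute {attribute!r} has a degenerate universe "
            f"[{universe_min}, {universe_max}]")
    if not K_MIN <= k <= K_MAX:
        raise ValueError(f"k must be in [{K_MIN}, {K_MAX}], got {k}")
    if labels is None:
        labels = default_labels(k)
    labels = tuple(str(lab) for lab in labels)
    if len(labels) != k or len(set(labels)) != k:
        raise ValueError(f"need {k} unique labels, got {labels!r}")

    span = universe_max - universe_min
    peaks = [universe_min + i * span / (k - 1) for i in range(k)]
    peaks[0], peaks[-1] = universe_min, universe_max
    mfs = []
    for i in range(k):
        a = peaks[i - 1] if i > 0 else peaks[0]
        c = peaks[i + 1] if i < k - 1 else peaks[-1]
        mfs.append(TriangularMF(labels[i], a, peaks[i], c))
    return FuzzyPartition(attribute, universe_min, universe_max, k, tuple(mfs))


@dataclass
class FuzzyDatabase:
    """The fuzzy database: one :class:`FuzzyPartition` per predictive attribute."""

    partitions: dict[str, FuzzyPartition]
    k_default: int = 3
    k_overrides: dict[str, int] = field(default_factory=dict)
    excluded: tuple[str, ...] = ()

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(self.partitions)

    def __getitem__(self, attribute: str) -> FuzzyPartition:
        return self.partitions[attribute]

    def __contains__(self, attribute: str) -> bool:
        return attribute in self.partitions

    def to_dict(self) -> dict:
        return {
            "k_default": self.k_default,
            "k_overrides": dict(self.k_overrides),
            "excluded": list(self.excluded),
            "partitions": {
                name: {
                    "universe_min": p.universe_min,
                    "universe_max": p.universe_max,
                    "k": p.k,
                    "mfs": [
                        {"label": m.label, "a": m.a, "b": m.b, "c": m.c}
                        for m in p.mfs
                    ],
                }
                for name, p in self.partitions.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzyDatabase":
        partitions = {}
        for name, pd_ in d["partitions"].items():
            mfs = tuple(
                TriangularMF(m["label"], float(m["a"]), float(m["b"]), float(m["c"]))
                for m in pd_["mfs"]
            )
            partitions[name] = FuzzyPartition(
                name, float(pd_["universe_min"]), float(pd_["universe_max"]),
                int(pd_["k"]), mfs)
        return cls(
            partitions=partitions,
            k_default=int(d.get("k_default", 3)),
            k_overrides={a: int(v) for a, v in d.get("k_overrides", {}).items()},
            excluded=tuple(d.get("excluded", ())),
        )

    def to_json(self, path=None, **kwargs) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_json(cls, path) -> "FuzzyDatabase":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_fuzzy_database(
    table: pd.DataFrame,
    k_default: int = 3,
    k_overrides: Mapping[str, int] | None = None,
    class_column: str = "class",
    labels: Mapping[int, Sequence[str]] | None = None,
) -> FuzzyDatabase:
    """Build partitions for every non-constant predictive column of ``table``.

    The universe of each attribute is its observed min/max over the *full*
    table (the split into training and testing folds happens after
    fuzzification).  Integer-valued attributes are treated exactly like
    continuous ones.  Constant attributes carry no information and the
    equalized-universe construction is undefined for them, so they are
    excluded with a warning.
    """
    k_overrides = dict(k_overrides or {})
    predictive = [c for c in table.columns if c != class_column]
    if not predictive:
        raise ValueError("table has no predictive attributes")
    unknown = set(k_overrides) - set(predictive)
    if unknown:
        raise KeyError(f"k_overrides name unknown attributes: {sorted(unknown)}")

    partitions: dict[str, FuzzyPartition] = {}
    excluded: list[str] = []
    for name in predictive:
        col = pd.to_numeric(table[name], errors="raise")
        lo, hi = float(col.min()), float(col.max())
        k = k_overrides.get(name, k_default)
        lab = labels.get(k) if labels else None
        try:
            partitions[name] = build_partition(name, lo, hi, k, labels=lab)
        except DegenerateUniverseError:
            excluded.append(name)
            warnings.warn(
                f"attribute {name!r} is constant at {lo}; excluded from the "
                "fuzzy database", stacklevel=2)
            logger.warning("excluding constant attribute %r (value %s)", name, lo)
    if not partitions:
        raise ValueError("no usable predictive attributes (all constant)")
    return FuzzyDatabase(partitions, k_default, k_overrides, tuple(excluded))
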