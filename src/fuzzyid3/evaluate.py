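"""Evaluation protocol: repeated stratified 10-fold cross-validation,
confusion-matrix metrics with macro-averaging, and the two-tailed t-test
comparing the fuzzy pipeline with plain ID3 on raw categorical values.

One run = one complete k-fold cross-validation under one shuffle seed; the
run's accuracy is the mean of its fold accuracies.  Repeating the CV for
``n_runs`` distinct seeds gives the mean and standard deviation reported, and
the per-run accuracies feed the t-test (paired mode, df = n_runs - 1, by
default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fuzzify import LinguisticTable, fuzzify_table
from .inference import classify_crisp, predict_crisp_table
from .membership import FuzzyDatabase, build_fuzzy_database
from .tree import induce_tree


# ---------------------------------------------------------------------------
# folds

def stratified_kfold_indices(
    class_column: Sequence[str], k: int, seed: int, stratified: bool = True
) -> np.ndarray:
    """Fold assignment (values 0..k-1) for every row.

    Stratified: each class's rows are shuffled and dealt cyclically, with the
    starting fold rotated between classes so fold sizes stay balanced; the
    per-fold count of each class differs from exact proportionality by at
    most 1.  Reproducible from ``seed``.
    """
    y = np.asarray(class_column, dtype=object)
    n = len(y)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if not stratified:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % k
        return folds
    offset = 0
    for cls in sorted(pd.unique(y)):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            warnings.warn(
                f"class {cls!r} has only {len(idx)} rows for {k} folds",
                stacklevel=2)
        idx = rng.permutation(idx)
        folds[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)
    return folds


# ---------------------------------------------------------------------------
# metrics

@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are actual classes, columns predicted."""

    classes: tuple[str, ...]
    counts: np.ndarray

    @classmethod
    def from_labels(
        cls,
        actual: Sequence[str],
        predicted: Sequence[str],
        classes: Sequence[str] | None = None,
    ) -> "ConfusionMatrix":
        actual = list(actual)
        predicted = list(predicted)
        if len(actual) != len(predicted):
            raise ValueError(
                f"length mismatch: {len(actual)} actual vs {len(predicted)} predicted")
        if not actual:
            raise ValueError("empty label sequences")
        if classes is None:
            classes = sorted(set(actual) | set(predicted))
        classes = tuple(classes)
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for a, p in zip(actual, predicted):
            counts[index[a], index[p]] += 1
        return cls(classes, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("cannot add confusion matrices over different classes")
        return ConfusionMatrix(self.classes, self.counts + other.counts)


@dataclass
class MetricsReport:
    """Accuracy plus macro-averaged precision/recall/F1 (all in [0,1]).

    A class never predicted gets precision 0 (and one never present gets
    recall 0) rather than being dropped, so the macro mean stays total.
    """

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: dict[str, dict[str, float]]
    sd_accuracy: float = 0.0
    n_runs: int = 1
    n_folds: int = 1
    seed_list: tuple[int, ...] = ()
    accuracy_pooled: float | None = None
    confusion: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": self.per_class,
            "sd_accuracy": self.sd_accuracy,
            "n_runs": self.n_runs,
            "n_folds": self.n_folds,
            "seed_list": list(self.seed_list),
        }
        if self.accuracy_pooled is not None:
            d["accuracy_pooled"] = self.accuracy_pooled
        if self.confusion is not None:
            d["confusion"] = {
                "classes": list(self.confusion.classes),
                "counts": self.confusion.counts.tolist(),
            }
        return d

    def format_table(self) -> str:
        """Plain-text report in percent, one row per aggregate metric."""
        lines = [
            f"{'Accuracy (%)':<16}{self.accuracy * 100:8.3f}",
            f"{'Precision (%)':<16}{self.macro_precision * 100:8.3f}",
            f"{'Recall (%)':<16}{self.macro_recall * 100:8.3f}",
            f"{'F1-measure (%)':<16}{self.macro_f1 * 100:8.3f}",
            f"{'SD':<16}{self.sd_accuracy:8.4f}",
        ]
        return "\n".join(lines)


def confusion_and_metrics(
    actual: Sequence[str],
    predicted: Sequence[str],
    classes: Sequence[str] | None = None,
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix plus accuracy and macro precision/recall/F1."""
    cm = ConfusionMatrix.from_labels(actual, predicted, classes)
    return cm, metrics_from_confusion(cm)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    counts = cm.counts
    total = counts.sum()
    accuracy = float(np.trace(counts)) / total
    per_class: dict[str, dict[str, float]] = {}
    for i, c in enumerate(cm.classes):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class[c] = {"precision": float(prec), "recall": float(rec),
                        "f1": float(f1)}
    macro = {m: float(np.mean([v[m] for v in per_class.values()]))
             for m in ("precision", "recall", "f1")}
    return MetricsReport(
        accuracy=accuracy,
        macro_precision=macro["precision"],
        macro_recall=macro["recall"],
        macro_f1=macro["f1"],
        per_class=per_class,
        confusion=cm,
    )


# ---------------------------------------------------------------------------
# t-test

@dataclass
class TTestResult:
    t_value: float
    df: int
    p_value: float
    alpha: float = 0.05
    two_tailed: bool = True
    mode: str = "paired"
    degenerate: bool = False  # zero variance of the differences

    @property
    def reject_null(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "t_value": self.t_value, "df": self.df, "p_value": self.p_value,
            "alpha": self.alpha, "two_tailed": self.two_tailed,
            "mode": self.mode, "reject_null": self.reject_null,
        }


def t_test(
    acc_a: Sequence[float],
    acc_b: Sequence[float],
    mode: Literal["paired", "pooled"] = "paired",
    alpha: float = 0.05,
) -> TTestResult:
    """Two-tailed t-test between two sets of run accuracies.

    Paired mode: ``t = mean(d) / (sd(d)/sqrt(n))`` with df = n-1 (sample SD,
    n-1 denominator).  Pooled mode: classic equal-variance two-sample test
    with df = 2n-2.  A zero-variance difference vector with nonzero mean is
    reported as an infinite t with p = 0; all-zero differences give t = 0,
    p = 1.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("accuracy vectors must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two runs per method")
    if mode == "paired":
        d = a - b
        df = n - 1
        sd = d.std(ddof=1)
        if sd == 0.0:
            if d.mean() == 0.0:
                return TTestResult(0.0, df, 1.0, alpha, mode=mode, degenerate=True)
            t = math.inf if d.mean() > 0 else -math.inf
            return TTestResult(t, df, 0.0, alpha, mode=mode, degenerate=True)
        t = d.mean() / (sd / math.sqrt(n))
    elif mode == "pooled":
        df = 2 * n - 2
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        if sp2 == 0.0:
            if a.mean() == b.mean():
                return TTestResult(0.0, df, 1.0, alpha, mode=mode, degenerate=True)
            t = math.inf if a.mean() > b.mean() else -math.inf
            return TTestResult(t, df, 0.0, alpha, mode=mode, degenerate=True)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * 2 / n)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), df, p, alpha, mode=mode)


# ---------------------------------------------------------------------------
# repeated CV

@dataclass
class EvalConfig:
    """Configuration of the repeated-CV protocol (defaults = study protocol)."""

    n_runs: int = 10
    n_folds: int = 10
    k_default: int = 3
    k_overrides: dict[str, int] = field(default_factory=dict)
    stratified: bool = True
    tie_break: str = "left"
    universe: Literal["full", "train"] = "full"
    baseline: bool = False
    t_test_mode: Literal["paired", "pooled"] = "paired"
    alpha: float = 0.05
    min_support: int = 1
    seed: int = 0


def _cv_one_run(
    ling: LinguisticTable,
    domains: Mapping[str, tuple[str, ...]],
    folds: np.ndarray,
    min_support: int = 1,
) -> tuple[float, list[str], list[str]]:
    """One k-fold CV pass on a fully fuzzified table.  Returns the mean fold
    accuracy plus the pooled actual/predicted labels."""
    df = ling.df
    class_column = ling.class_column
    fold_accs: list[float] = []
    actual_all: list[str] = []
    pred_all: list[str] = []
    for f in range(folds.max() + 1):
        train = LinguisticTable(df[folds != f], ling.attributes, class_column)
        test = df[folds == f]
        tree = induce_tree(train, domains, min_support=min_support)
        preds = list(predict_crisp_table(tree, test))
        actual = list(test[class_column])
        fold_accs.append(
            float(np.mean([p == a for p, a in zip(preds, actual)])))
        actual_all.extend(actual)
        pred_all.extend(preds)
    return float(np.mean(fold_accs)), actual_all, pred_all


def _aggregate_runs(
    run_accs: list[float],
    run_cms: list[ConfusionMatrix],
    n_pooled_correct: int,
    n_pooled: int,
    config: EvalConfig,
    seeds: list[int],
) -> MetricsReport:
    # macro metrics per run (from the run's pooled confusion), averaged over runs
    per_run = [metrics_from_confusion(cm) for cm in run_cms]
    per_class: dict[str, dict[str, float]] = {}
    for c in run_cms[0].classes:
        per_class[c] = {
            m: float(np.mean([r.per_class[c][m] for r in per_run]))
            for m in ("precision", "recall", "f1")
        }
    total_cm = run_cms[0]
    for cm in run_cms[1:]:
        total_cm = total_cm + cm
    accs = np.asarray(run_accs)
    return MetricsReport(
        accuracy=float(accs.mean()),
        macro_precision=float(np.mean([r.macro_precision for r in per_run])),
        macro_recall=float(np.mean([r.macro_recall for r in per_run])),
        macro_f1=float(np.mean([r.macro_f1 for r in per_run])),
        per_class=per_class,
        sd_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        n_runs=config.n_runs,
        n_folds=config.n_folds,
        seed_list=tuple(seeds),
        accuracy_pooled=n_pooled_correct / n_pooled,
        confusion=total_cm,
    )


class UnsupportedDataError(ValueError):
    """Plain ID3 requested on data it cannot represent categorically."""


def _categorical_view(
    raw: pd.DataFrame, class_column: str
) -> tuple[LinguisticTable, dict[str, tuple[str, ...]]]:
    """Plain-ID3 view: raw values as categorical labels.  Only integer-valued
    attributes qualify; real-valued data is rejected, mirroring the protocol's
    'method does not support the classification' entries."""
    out = {}
    domains = {}
    attrs = [c for c in raw.columns if c != class_column]
    for name in attrs:
        col = pd.to_numeric(raw[name], errors="raise").to_numpy(dtype=float)
        if not np.allclose(col, np.round(col), atol=0.0):
            raise UnsupportedDataError(
                f"plain ID3 cannot classify real-valued attribute {name!r}")
        labels = np.char.mod("%d", np.round(col).astype(int))
        out[name] = labels
        domains[name] = tuple(sorted(set(labels.tolist()), key=int))
    out[class_column] = raw[class_column].astype(str).to_numpy()
    df = pd.DataFrame(out, index=raw.index)[list(attrs) + [class_column]]
    return LinguisticTable(df.reset_index(drop=True), tuple(attrs), class_column), domains


@dataclass
class CVComparison:
    """Repeated-CV results for the fuzzy pipeline and (optionally) plain ID3."""

    fid3: MetricsReport
    run_accuracies: dict[str, list[float]]
    id3: MetricsReport | None = None
    id3_error: str | None = None
    ttest: TTestResult | None = None

    def to_dict(self) -> dict:
        d = {"fid3": self.fid3.to_dict(),
             "run_accuracies": self.run_accuracies}
        if self.id3 is not None:
            d["id3"] = self.id3.to_dict()
        if self.id3_error is not None:
            d["id3_error"] = self.id3_error
        if self.ttest is not None:
            d["t_test"] = self.ttest.to_dict()
        return d


def run_repeated_cv(
    raw: pd.DataFrame,
    config: EvalConfig | None = None,
    class_column: str = "class",
) -> CVComparison:
    """The full evaluation protocol on a raw numeric table.

    The fuzzy database is built on the complete table and the whole dataset
    is fuzzified before any train/test split (``config.universe='train'``
    instead rebuilds the database per fold from training rows only).  Each
    run shuffles the stratified folds under its own seed derived from
    ``config.seed``; the same folds are reused for the plain-ID3 baseline so
    the t-test is naturally paired.
    """
    config = config or EvalConfig()
    seeds = [int(config.seed) + r for r in range(config.n_runs)]

    db = build_fuzzy_database(
        raw, config.k_default, config.k_overrides, class_column)
    domains = {name: part.labels for name, part in db.partitions.items()}
    ling_full = fuzzify_table(raw, db, class_column, config.tie_break)
    y = raw[class_column].astype(str).to_numpy()

    base_view = None
    base_domains = None
    id3_error = None
    if config.baseline:
        try:
            base_view, base_domains = _categorical_view(raw, class_column)
        except UnsupportedDataError as exc:
            id3_error = str(exc)

    fid3_accs: list[float] = []
    id3_accs: list[float] = []
    fid3_cms: list[ConfusionMatrix] = []
    id3_cms: list[ConfusionMatrix] = []
    fid3_correct = fid3_total = 0
    id3_correct = id3_total = 0
    classes = tuple(sorted(set(y.tolist())))

    for run_seed in seeds:
        folds = stratified_kfold_indices(
            y, config.n_folds, run_seed, config.stratified)
        if config.universe == "full":
            acc, actual, pred = _cv_one_run(
                ling_full, domains, folds, config.min_support)
        else:
            acc, actual, pred = _cv_train_universe_run(
                raw, config, class_column, folds)
        fid3_accs.append(acc)
        fid3_cms.append(ConfusionMatrix.from_labels(actual, pred, classes))
        fid3_correct += sum(p == a for p, a in zip(pred, actual))
        fid3_total += len(actual)
        if base_view is not None:
            acc_b, actual_b, pred_b = _cv_one_run(
                base_view, base_domains, folds, config.min_support)
            id3_accs.append(acc_b)
            id3_cms.append(ConfusionMatrix.from_labels(actual_b, pred_b, classes))
            id3_correct += sum(p == a for p, a in zip(pred_b, actual_b))
            id3_total += len(actual_b)

    fid3_report = _aggregate_runs(
        fid3_accs, fid3_cms, fid3_correct, fid3_total, config, seeds)
    result = CVComparison(
        fid3=fid3_report,
        run_accuracies={"fid3": fid3_accs},
        id3_error=id3_error,
    )
    if id3_accs:
        result.id3 = _aggregate_runs(
            id3_accs, id3_cms, id3_correct, id3_total, config, seeds)
        result.run_accuracies["id3"] = id3_accs
        result.ttest = t_test(
            fid3_accs, id3_accs, config.t_test_mode, config.alpha)
    return result


def _cv_train_universe_run(
    raw: pd.DataFrame,
    config: EvalConfig,
    class_column: str,
    folds: np.ndarray,
) -> tuple[float, list[str], list[str]]:
    """Leakage-free variant: per fold, build the fuzzy database from training
    rows only and fuzzify train and test with it (test values clamped)."""
    fold_accs: list[float] = []
    actual_all: list[str] = []
    pred_all: list[str] = []
    for f in range(folds.max() + 1):
        train_raw = raw[folds != f]
        test_raw = raw[folds == f]
        db = build_fuzzy_database(
            train_raw, config.k_default, config.k_overrides, class_column)
        domains = {name: part.labels for name, part in db.partitions.items()}
        train = fuzzify_table(train_raw, db, class_column, config.tie_break)
        test = fuzzify_table(test_raw, db, class_column, config.tie_break)
        tree = induce_tree(train, domains, min_support=config.min_support)
        preds = [classify_crisp(tree, row).predicted_class
                 for row in test.iter_rows()]
        actual = list(test.class_labels())
        fold_accs.append(float(np.mean([p == a for p, a in zip(preds, actual)])))
        actual_all.extend(actual)
        pred_all.extend(preds)
    return float(np.mean(fold_accs)), actual_all, pred_all
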