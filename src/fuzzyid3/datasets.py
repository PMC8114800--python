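"""Schema-driven reading of delimited clinical tables.

Handles the common UCI dialects: positional ID columns to drop, a positional
class column with an optional raw-to-label map, and a missing-value marker
triggering listwise deletion.  Presets are bundled for the three
breast-cancer dialects (Wisconsin original, Wisconsin diagnostic, Coimbra);
none of them requires a download — they only describe the file layout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

WDBC_FEATURES = [
    "radius", "texture", "perimeter", "area", "smoothness", "compactness",
    "concavity", "concave_points", "symmetry", "fractal_dimension",
]


@dataclass
class TableSchema:
    """Layout of a delimited file: what to drop, where the class lives, and
    how missing values are marked."""

    delimiter: str = ","
    has_header: bool = False
    id_columns: tuple[int, ...] = ()
    class_column: int = -1
    class_map: dict[str, str] = field(default_factory=dict)
    missing_marker: str = "?"
    column_names: tuple[str, ...] | None = None  # applied when no header

    def __post_init__(self) -> None:
        if self.class_column in self.id_columns:
            raise ValueError("class column cannot also be an ID column")

    @classmethod
    def from_dict(cls, d: Mapping) -> "TableSchema":
        return cls(
            delimiter=d.get("delimiter", ","),
            has_header=bool(d.get("has_header", False)),
            id_columns=tuple(d.get("id_columns", ())),
            class_column=int(d.get("class_column", -1)),
            class_map={str(k): str(v) for k, v in d.get("class_map", {}).items()},
            missing_marker=str(d.get("missing_marker", "?")),
            column_names=tuple(d["column_names"]) if d.get("column_names") else None,
        )


def _wdbc_names() -> tuple[str, ...]:
    names = ["id", "diagnosis"]
    for stat in ("mean", "se", "worst"):
        names += [f"{stat}_{f}" for f in WDBC_FEATURES]
    return tuple(names)


SCHEMA_PRESETS: dict[str, TableSchema] = {
    # Wisconsin original: id, 9 integer attributes (1-10), class 2=benign 4=malignant
    "wbcd": TableSchema(
        has_header=False,
        id_columns=(0,),
        class_column=10,
        class_map={"2": "benign", "4": "malignant"},
        missing_marker="?",
        column_names=(
            "id", "clump_thickness", "cell_size_uniformity",
            "cell_shape_uniformity", "marginal_adhesion",
            "single_epithelial_cell_size", "bare_nuclei", "bland_chromatin",
            "normal_nucleoli", "mitoses", "class",
        ),
    ),
    # Wisconsin diagnostic: id, M/B class, 30 real-valued features
    "wdbc": TableSchema(
        has_header=False,
        id_columns=(0,),
        class_column=1,
        class_map={"M": "malignant", "B": "benign"},
        missing_marker="?",
        column_names=_wdbc_names(),
    ),
    # Coimbra: header row, 9 numeric attributes, class 1=healthy 2=patient
    "coimbra": TableSchema(
        has_header=True,
        id_columns=(),
        class_column=9,
        class_map={"1": "healthy", "2": "patient"},
        missing_marker="?",
    ),
    # generic: header row, class in the last column, no IDs
    "plain": TableSchema(has_header=True, class_column=-1),
}

#: fuzzy-set count overrides used with the diagnostic dialect (all other
#: attributes keep the default of three sets)
WDBC_K_OVERRIDES = {"se_radius": 5, "worst_radius": 5}


def load_schema(name_or_path: str) -> TableSchema:
    """A preset name (wbcd/wdbc/coimbra/plain) or a JSON/YAML schema file."""
    if name_or_path in SCHEMA_PRESETS:
        return SCHEMA_PRESETS[name_or_path]
    text = open(name_or_path).read()
    try:
        d = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        d = yaml.safe_load(text)
    return TableSchema.from_dict(d)


def read_table(path, schema: TableSchema | str = "plain") -> pd.DataFrame:
    """Read a delimited file into a raw numeric table.

    ID columns are dropped; any row containing the missing marker in a
    retained column is deleted (listwise); the class column is mapped through
    ``class_map`` and renamed ``class``; every predictive cell must parse as
    a number.  A read report (rows in / dropped / out) is logged.
    """
    if isinstance(schema, str):
        schema = load_schema(schema)
    df = pd.read_csv(
        path,
        sep=schema.delimiter,
        header=0 if schema.has_header else None,
        dtype=str,
        skipinitialspace=True,
    )
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    ncols = df.shape[1]
    if not schema.has_header:
        if schema.column_names:
            if len(schema.column_names) != ncols:
                raise ValueError(
                    f"schema names {len(schema.column_names)} columns but the "
                    f"file has {ncols}")
            df.columns = list(schema.column_names)
        else:
            df.columns = [f"col{i}" for i in range(ncols)]

    class_pos = schema.class_column % ncols
    for pos in schema.id_columns:
        if not -ncols <= pos < ncols:
            raise IndexError(f"id column {pos} out of bounds for {ncols} columns")
    drop = {p % ncols for p in schema.id_columns}
    keep = [i for i in range(ncols) if i not in drop]
    if class_pos in drop:
        raise ValueError("class column was dropped as an ID column")
    df = df.iloc[:, keep]
    class_name = df.columns[keep.index(class_pos)]

    n_in = len(df)
    mask = df.apply(lambda col: col.astype(str).str.strip() == schema.missing_marker)
    rows_missing = mask.any(axis=1)
    df = df[~rows_missing]
    n_dropped = int(rows_missing.sum())
    if df.empty:
        raise ValueError(
            f"all {n_in} rows of {path} were deleted (missing marker "
            f"{schema.missing_marker!r})")

    out = {}
    for col in df.columns:
        if col == class_name:
            continue
        try:
            out[col] = pd.to_numeric(df[col].str.strip(), errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col].str.strip(), errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"unparsable numeric cell in column {col!r}, row {row}: "
                f"{bad.iloc[0] if len(bad) else ''!r}") from exc
    cls = df[class_name].str.strip()
    if schema.class_map:
        unmapped = set(cls.unique()) - set(schema.class_map)
        if unmapped:
            raise ValueError(
                f"class values {sorted(unmapped)} missing from class_map")
        cls = cls.map(schema.class_map)
    out["class"] = cls
    result = pd.DataFrame(out).reset_index(drop=True)
    # keep original column order, class last only if it was last
    ordered = [c if c != class_name else "class" for c in df.columns]
    result = result[ordered]
    logger.info(
        "read %s: %d rows in, %d deleted listwise, %d out",
        path, n_in, n_dropped, len(result))
    return result
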