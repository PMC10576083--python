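"""Schema-validated delimited-text readers and writers.

All tables are comma-separated UTF-8 with a header row; booleans are
serialized as ``true``/``false``; missing values are disallowed in
required columns. ``validate_table`` enforces column names, value domains
(grades, flags, non-negative integers) and key uniqueness, reporting
row-numbered errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import TableValidationError
from .simulate import CLASSES, GRADES

_BOOL_MAP = {"true": True, "false": False}


@dataclass(frozen=True)
class ColumnSpec:
    kind: str  # "str" | "int" | "float" | "bool"
    min: float | None = None
    allowed: tuple[str, ...] | None = None


SCHEMAS: dict[str, dict] = {
    "nuclei": {
        "columns": {
            "tumor_id": ColumnSpec("str"),
            "field_id": ColumnSpec("int", min=1),
            "nucleus_id": ColumnSpec("str"),
            "spots_chr7": ColumnSpec("int", min=0),
            "spots_chr11": ColumnSpec("int", min=0),
            "spots_chr16": ColumnSpec("int", min=0),
            "area_um2": ColumnSpec("float", min=np.nextafter(0, 1)),
            "dapi_integrated": ColumnSpec("float", min=np.nextafter(0, 1)),
            "hnf4a_pos": ColumnSpec("bool"),
            "ki67_pos": ColumnSpec("bool"),
            "is_tumor": ColumnSpec("bool"),
        },
        "unique": ("tumor_id", "nucleus_id"),
    },
    "ihc": {
        "columns": {
            "tumor_id": ColumnSpec("str"),
            "ube2c_grade": ColumnSpec("str", allowed=GRADES),
            "aurka_grade": ColumnSpec("str", allowed=GRADES),
            "top2a_grade": ColumnSpec("str", allowed=GRADES),
            "pgcc_per_field": ColumnSpec("float", min=0),
        },
        "unique": ("tumor_id",),
    },
    "clinical": {
        "columns": {
            "tumor_id": ColumnSpec("str"),
            "afp_ng_ml": ColumnSpec("float", min=np.nextafter(0, 1)),
            "true_class": ColumnSpec("str", allowed=CLASSES),
        },
        "unique": ("tumor_id",),
    },
    "survival": {
        "columns": {
            "tumor_id": ColumnSpec("str"),
            "time_years": ColumnSpec("float", min=np.nextafter(0, 1)),
            "event": ColumnSpec("bool"),
        },
        "unique": ("tumor_id",),
    },
    "tumor_profiles": {
        "columns": {
            "tumor_id": ColumnSpec("str"),
            "c7": ColumnSpec("int", min=1),
            "c11": ColumnSpec("int", min=1),
            "c16": ColumnSpec("int", min=1),
            "average_ploidy": ColumnSpec("float", min=np.nextafter(0, 1)),
            "call": ColumnSpec("str", allowed=CLASSES),
            "n_nuclei_used": ColumnSpec("int", min=1),
            "n_fields": ColumnSpec("int", min=1),
            "qc_pass": ColumnSpec("bool"),
        },
        "unique": ("tumor_id",),
    },
    "cytometry": {
        "columns": {
            "tumor_id": ColumnSpec("str"),
            "median_c": ColumnSpec("float", min=np.nextafter(0, 1)),
            "median_area_um2": ColumnSpec("float", min=np.nextafter(0, 1)),
            "frac_2c": ColumnSpec("float", min=0),
            "frac_4c": ColumnSpec("float", min=0),
            "frac_8c": ColumnSpec("float", min=0),
            "frac_ge8c": ColumnSpec("float", min=0),
        },
        "unique": ("tumor_id",),
    },
    "pub": {
        "columns": {
            "tumor_id": ColumnSpec("str"),
            "baseline_area_um2": ColumnSpec("float", min=np.nextafter(0, 1)),
            "pgcc_density": ColumnSpec("float", min=0),
            "pgcc_abundant": ColumnSpec("bool"),
            "ube2c_grade": ColumnSpec("str", allowed=GRADES),
            "pub_score": ColumnSpec("int", min=0),
        },
        "unique": ("tumor_id",),
    },
    "km_curves": {
        "columns": {
            "group": ColumnSpec("str"),
            "time": ColumnSpec("float", min=0),
            "survival": ColumnSpec("float", min=0),
            "at_risk": ColumnSpec("float", min=0),
        },
        "unique": None,
    },
}


def write_table(df: pd.DataFrame, path, schema_name: str) -> None:
    """Write a table in the canonical CSV form for its schema."""
    schema = SCHEMAS[schema_name]
    cols = list(schema["columns"])
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableValidationError(
            f"{schema_name}: cannot write, missing columns {missing}", []
        )
    out = df[cols].copy()
    for name, spec in schema["columns"].items():
        if spec.kind == "bool":
            out[name] = out[name].astype(bool).map({True: "true", False: "false"})
    out.to_csv(path, index=False)


def _convert_column(raw: pd.Series, spec: ColumnSpec, name: str, errors: list[str]):
    """Convert one string column to its schema type, recording row errors."""
    values = raw.astype("string")
    result = pd.Series([None] * len(values), dtype=object)
    for idx, v in values.items():
        row = idx + 2  # 1-based with header row
        if pd.isna(v) or v == "":
            errors.append(f"row {row}, column {name}: missing value")
            continue
        if spec.kind == "bool":
            if v.lower() not in _BOOL_MAP:
                errors.append(f"row {row}, column {name}: expected true/false, got {v!r}")
                continue
            result[idx] = _BOOL_MAP[v.lower()]
        elif spec.kind == "int":
            try:
                f = float(v)
                if f != int(f):
                    raise ValueError
                parsed = int(f)
            except ValueError:
                errors.append(f"row {row}, column {name}: expected an integer, got {v!r}")
                continue
            if spec.min is not None and parsed < spec.min:
                errors.append(f"row {row}, column {name}: value {parsed} below minimum {spec.min:g}")
                continue
            result[idx] = parsed
        elif spec.kind == "float":
            try:
                parsed = float(v)
            except ValueError:
                errors.append(f"row {row}, column {name}: expected a number, got {v!r}")
                continue
            if not np.isfinite(parsed):
                errors.append(f"row {row}, column {name}: non-finite value {v!r}")
                continue
            if spec.min is not None and parsed < spec.min:
                errors.append(f"row {row}, column {name}: value {parsed:g} below minimum {spec.min:g}")
                continue
            result[idx] = parsed
        else:  # str
            if spec.allowed is not None and v.strip().lower() not in spec.allowed:
                errors.append(
                    f"row {row}, column {name}: {v!r} not in allowed values "
                    f"{{{', '.join(spec.allowed)}}}"
                )
                continue
            result[idx] = v.strip().lower() if spec.allowed is not None else v
    return result


def validate_table(source, schema_name: str) -> tuple[pd.DataFrame, list[str]]:
    """Validate a CSV file (or raw DataFrame) against a named schema.

    Returns the type-converted table and the list of itemized errors
    (empty when the table is valid). Rows with errors keep placeholder
    values; callers requiring validity should use :func:`read_table`.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    if isinstance(source, pd.DataFrame):
        raw = source.astype(str)
    else:
        raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    errors: list[str] = []
    missing = [c for c in schema["columns"] if c not in raw.columns]
    for c in missing:
        errors.append(f"missing required column: {c}")
    if missing:
        return raw, errors

    converted = pd.DataFrame(index=raw.index)
    for name, spec in schema["columns"].items():
        converted[name] = _convert_column(raw[name], spec, name, errors)
    if not errors:
        for name, spec in schema["columns"].items():
            dtype = {"int": np.int64, "float": float, "bool": bool}.get(spec.kind, object)
            converted[name] = converted[name].astype(dtype)
    key = schema["unique"]
    if key and not errors:
        dup = converted.duplicated(subset=list(key))
        for idx in converted.index[dup]:
            keyval = tuple(converted.loc[idx, list(key)])
            errors.append(f"row {idx + 2}: duplicate key {key} = {keyval}")
    return converted, errors


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a table, raising on any schema violation."""
    df, errors = validate_table(path, schema_name)
    if errors:
        preview = "; ".join(errors[:5])
        more = f" (+{len(errors) - 5} more)" if len(errors) > 5 else ""
        raise TableValidationError(
            f"{path}: {len(errors)} validation error(s): {preview}{more}", errors
        )
    return df
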