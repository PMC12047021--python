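"""CSV schemas and validated table I/O.

All interchange is CSV (UTF-8, dot decimal); concentrations are always
mg a.s./kg dry soil.  Each schema lists its mandatory columns and
row-level checks; unknown columns are preserved untouched.  Violations
are collected and reported together rather than failing on the first.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .synthetic import pack_sizes, unpack_sizes

#: schema name -> (mandatory columns, row checks)
SCHEMAS: dict[str, dict] = {
    "monitoring": {
        "columns": ["site", "pesticide", "sample_id", "concentration", "below_loq"],
        "nonneg": ["concentration"],
    },
    "ecotox": {
        "columns": ["pesticide", "species", "endpoint_type", "effect", "value"],
        "positive": ["value"],
        "categorical": {"endpoint_type": ("NOEC", "EC50", "LC50")},
    },
    "pesticide_info": {
        "columns": ["name", "class", "log_pow", "dt50_days",
                    "approval_end_date", "application_rate"],
        "positive_or_blank": ["dt50_days", "application_rate"],
    },
    "reproduction": {
        "columns": ["site", "treatment", "replicate", "introduced",
                    "adults_surviving", "juveniles", "adult_sizes"],
        "nonneg": ["adults_surviving", "juveniles"],
    },
    "exposure": {
        "columns": ["css", "pesticide", "mec_mg_kg", "pec_mg_kg", "five_pec_mg_kg"],
        "nonneg": ["mec_mg_kg", "pec_mg_kg", "five_pec_mg_kg"],
    },
    "noec": {
        "columns": ["pesticide", "noec_mg_kg"],
        "positive": ["noec_mg_kg"],
    },
}


def validate_table(df: pd.DataFrame, schema: str) -> list[str]:
    """Return the list of row-level violations (empty = valid).

    A missing mandatory column raises :class:`SchemaError` naming it.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    for col in spec["columns"]:
        if col not in df.columns:
            raise SchemaError(f"schema {schema!r}: missing mandatory column {col!r}")
    violations = []
    for col in spec.get("nonneg", []):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals < 0]
        violations += [f"{schema}.{col} row {i}: negative value {df.loc[i, col]}" for i in bad]
    for col in spec.get("positive", []):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~(vals > 0)]
        violations += [f"{schema}.{col} row {i}: non-positive value {df.loc[i, col]}" for i in bad]
    for col in spec.get("positive_or_blank", []):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.notna() & ~(vals > 0)]
        violations += [f"{schema}.{col} row {i}: non-positive value {df.loc[i, col]}" for i in bad]
    for col, allowed in spec.get("categorical", {}).items():
        bad = df.index[~df[col].isin(allowed)]
        violations += [
            f"{schema}.{col} row {i}: {df.loc[i, col]!r} not in {allowed}" for i in bad
        ]
    return violations


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate one CSV against a named schema."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path)
    violations = validate_table(df, schema)
    if violations:
        raise ValidationError(violations)
    if schema == "reproduction":
        df["adult_sizes"] = df["adult_sizes"].map(unpack_sizes)
    return df


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> Path:
    """Write one table; reproduction size lists are packed for CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    if schema == "reproduction" and "adult_sizes" in out.columns:
        out["adult_sizes"] = out["adult_sizes"].map(
            lambda s: pack_sizes(s) if isinstance(s, (list, tuple, np.ndarray)) else s
        )
    out.to_csv(path, index=False)
    return path


def jsonify(obj):
    """Recursively convert numpy/pandas scalars for json.dumps."""
    if isinstance(obj, dict):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return [jsonify(r) for r in obj.to_dict(orient="records")]
    return obj
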