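"""CSV table and JSON payload input/output.

Tables are plain CSV with a header row and numeric columns; payloads are
self-describing JSON objects stamped with a schema version and a ``method``
tag.  Secret keys are never written anywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError

SCHEMA_VERSION = 1

_FORBIDDEN_KEYS = {"secret", "secret_key", "seed_key", "key"}


def read_table(path) -> pd.DataFrame:
    """Read a CSV data table (header row, numeric columns).

    A non-numeric cell raises a :class:`ValidationError` naming the 1-based
    data row and the column.
    """
    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    for col in table.columns:
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValidationError(
                f"non-numeric value {table[col][bad.idxmax()]!r} at row {row}, "
                f"column {col!r} of {path}"
            )
        table[col] = converted.astype(float)
    return table


def write_table(table: pd.DataFrame, path) -> None:
    """Write a data table as CSV with full float precision."""
    table.to_csv(path, index=False, float_format="%.17g")


def _scrub_check(obj, where="payload") -> None:
    if isinstance(obj, dict):
        for key, value in obj.items():
            if str(key).lower() in _FORBIDDEN_KEYS:
                raise SchemaError(f"refusing to serialize key {key!r} in {where}")
            _scrub_check(value, where)
    elif isinstance(obj, (list, tuple)):
        for value in obj:
            _scrub_check(value, where)


def write_payload(payload, path) -> None:
    """Serialize a plot payload (object or dict) to JSON.

    The payload must carry ``kind`` and ``method``; a schema version is
    stamped on write.  Keys that look like secret material are refused.
    """
    if hasattr(payload, "to_dict"):
        payload = payload.to_dict()
    if not isinstance(payload, dict):
        raise SchemaError("payload must be a dict or expose to_dict()")
    for key in ("kind", "method"):
        if key not in payload:
            raise SchemaError(f"payload missing required field {key!r}")
    _scrub_check(payload)
    out = {"schema_version": SCHEMA_VERSION, **payload}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
        fh.write("\n")


def read_payload(path) -> dict:
    """Read a payload JSON file back, validating its schema."""
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict):
        raise SchemaError("payload file does not contain a JSON object")
    version = payload.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported or missing schema_version: {version!r}")
    for key in ("kind", "method"):
        if key not in payload:
            raise SchemaError(f"payload missing required field {key!r}")
    return payload
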