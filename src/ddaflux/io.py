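"""Deterministic tabular writers (CSV and JSON records).

CSV carries 6 significant digits for floats; JSON keeps full double
precision.  Column order is deterministic: the ``columns`` argument if
given, otherwise the key order of the first record.  Identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["write_records", "format_cell"]


def format_cell(value) -> str:
    """One CSV cell: floats to 6 significant digits, None/NaN empty."""
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return f"{value:.6g}"
    return str(value)


def _normalise(records) -> list[dict]:
    if isinstance(records, pd.DataFrame):
        return records.to_dict("records")
    return [dict(r) for r in records]


def write_records(
    records: Iterable[Mapping] | pd.DataFrame,
    format: str = "csv",
    path: str | Path | None = None,
    columns: Sequence[str] | None = None,
) -> str:
    """Serialise homogeneous flat records to CSV or JSON.

    Returns the serialised text; writes it to ``path`` when given.  With
    zero records and explicit ``columns``, CSV output is header-only.
    """
    if format not in ("csv", "json"):
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")
    if isinstance(records, pd.DataFrame) and columns is None:
        columns = list(records.columns)
    rows = _normalise(records)
    if columns is None:
        if not rows:
            raise ValueError("columns are required when writing zero records")
        columns = list(rows[0])

    if format == "csv":
        import io as _io

        buffer = _io.StringIO()
        writer = csv.writer(buffer, lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow([format_cell(row.get(c)) for c in columns])
        text = buffer.getvalue()
    else:
        clean = [
            {c: (None if isinstance(row.get(c), float) and math.isnan(row[c])
                 else row.get(c)) for c in columns}
            for row in rows
        ]
        text = json.dumps(clean, indent=2) + "\n"

    if path is not None:
        Path(path).write_text(text)
    return text
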