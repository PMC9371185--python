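"""Session file I/O.

Two equivalent on-disk dialects:

* **CSV** — one header row ``t,temp_c,humidity_pct,noise_db,brightness_lx,
  pressure_kpa,gsr,hr_bpm,ax,ay,az``; session metadata in a sidecar JSON file
  ``<stem>.meta.json`` next to the data file.
* **JSON lines** — one record object per line using the same field names;
  metadata in the same sidecar.

Missing channels are empty CSV cells / ``null`` JSON values and round-trip to
``None``.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Optional

from .types import Session, SensorRecord, ValidationError

__all__ = ["read_session", "write_session", "ParseError", "CSV_COLUMNS"]

CSV_COLUMNS = (
    "t",
    "temp_c",
    "humidity_pct",
    "noise_db",
    "brightness_lx",
    "pressure_kpa",
    "gsr",
    "hr_bpm",
    "ax",
    "ay",
    "az",
)

# file column -> SensorRecord field
_FIELD_OF = {
    "temp_c": "temperature",
    "humidity_pct": "humidity",
    "noise_db": "noise",
    "brightness_lx": "brightness",
    "pressure_kpa": "air_pressure",
    "gsr": "gsr",
    "hr_bpm": "heart_rate",
    "ax": "ax",
    "ay": "ay",
    "az": "az",
}

_META_KEYS = (
    "child_id",
    "gender",
    "age",
    "task_accuracy",
    "assessor_attention_label",
    "assessor_stress_label",
    "start_time",
    "session_id",
)


class ParseError(ValueError):
    """A malformed session file; the message names the offending row."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix == "" else path.with_name(path.stem + ".meta.json")


def _parse_cell(raw: Optional[str], column: str, row: int):
    if raw is None or raw == "":
        return None
    try:
        value = float(raw)
    except ValueError as exc:
        raise ParseError(f"row {row}: non-numeric value {raw!r} in column {column!r}") from exc
    if not math.isfinite(value):
        raise ParseError(f"row {row}: non-finite value in column {column!r}")
    return value


def _record_from_row(row_values: dict, row: int) -> SensorRecord:
    t_raw = row_values.get("t")
    if t_raw in (None, ""):
        raise ParseError(f"row {row}: missing timestamp")
    t = _parse_cell(str(t_raw), "t", row)
    if t != int(t):
        raise ParseError(f"row {row}: timestamp {t!r} is not on the 1 Hz integer grid")
    kwargs = {}
    for col, fld in _FIELD_OF.items():
        raw = row_values.get(col)
        kwargs[fld] = _parse_cell(str(raw) if raw is not None else None, col, row)
    try:
        return SensorRecord(timestamp=int(t), **kwargs)
    except ValidationError as exc:
        raise ParseError(f"row {row}: {exc}") from exc


def read_session(path: str | Path, format: Optional[str] = None) -> Session:
    """Read a session from ``path`` (``csv`` or ``jsonl``; inferred from suffix).

    Records are sorted by timestamp; duplicate timestamps are rejected and
    grid gaps are preserved (inspect :attr:`Session.gaps`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("jsonl" if path.suffix == ".jsonl" else "csv")
    if fmt not in ("csv", "jsonl"):
        raise ValidationError(f"unknown session format {fmt!r}")

    records: list[SensorRecord] = []
    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise ParseError(f"{path}: empty session file")
            unknown = set(reader.fieldnames) - set(CSV_COLUMNS)
            if unknown or "t" not in reader.fieldnames:
                raise ParseError(f"{path}: header does not match the session schema (unexpected: {sorted(unknown)})")
            for i, row in enumerate(reader, start=2):  # row 1 is the header
                records.append(_record_from_row(row, i))
    else:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"row {i}: invalid JSON") from exc
                records.append(_record_from_row(obj, i))
    if not records:
        raise ParseError(f"{path}: session contains no records")

    records.sort(key=lambda r: r.timestamp)
    for a, b in zip(records, records[1:]):
        if a.timestamp == b.timestamp:
            raise ParseError(f"duplicate timestamp t={a.timestamp}")

    meta_path = _sidecar(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"missing session metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    kwargs = {k: meta.get(k) for k in _META_KEYS}
    return Session(records=records, **kwargs)


def write_session(session: Session, path: str | Path, format: Optional[str] = None) -> Path:
    """Write ``session`` to ``path`` plus its metadata sidecar; returns the path."""
    path = Path(path)
    fmt = format or ("jsonl" if path.suffix == ".jsonl" else "csv")
    if fmt not in ("csv", "jsonl"):
        raise ValidationError(f"unknown session format {fmt!r}")
    path.parent.mkdir(parents=True, exist_ok=True)

    def row_of(r: SensorRecord) -> dict:
        out = {"t": r.timestamp}
        for col, fld in _FIELD_OF.items():
            out[col] = getattr(r, fld)
        return out

    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(CSV_COLUMNS))
            writer.writeheader()
            for r in session.records:
                row = row_of(r)
                writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
    else:
        with open(path, "w") as fh:
            for r in session.records:
                fh.write(json.dumps(row_of(r)) + "\n")

    meta = {k: getattr(session, k) for k in _META_KEYS}
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path
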