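"""Readers and writers for the canonical record/curve formats.

records.csv
    header ``record_id,fev1_fvc_ratio,tlc_pct_pred,dlco_pct_pred,clinician_text``
    (RFC 4180 quoting, UTF-8). Empty cells mean "not measured" and map to
    absent fields, never to zero. JSON equivalent: a list of objects with the
    same keys (missing/null keys are absent fields).

curves.csv
    long format, header ``record_id,volume_expired_l,flow_l_s``; points are
    grouped per id and sorted by volume (the only silent repair performed).
    JSON equivalent: ``{record_id: [[volume, flow], ...], ...}``.

Floats are written with ``repr`` (shortest round-tripping form) so
write-then-read is the identity at stored precision and reruns are
byte-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ParseError, ValidationError
from .types import MIN_CURVE_POINTS, FlowVolumeCurve, PFTRecord

__all__ = [
    "RECORD_FIELDS",
    "read_records",
    "write_records",
    "read_curves",
    "write_curves",
]

RECORD_FIELDS = ("record_id", "fev1_fvc_ratio", "tlc_pct_pred", "dlco_pct_pred", "clinician_text")
_NUMERIC_FIELDS = ("fev1_fvc_ratio", "tlc_pct_pred", "dlco_pct_pred")
CURVE_FIELDS = ("record_id", "volume_expired_l", "flow_l_s")

PathLike = Union[str, Path]


def _parse_cell(raw: Optional[str], row: int, column: str) -> Optional[float]:
    if raw is None or raw.strip() == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise ParseError(f"row {row}, column {column!r}: cannot parse number from {raw!r}")


def _infer_format(path: PathLike, format: Optional[str]) -> str:
    if format:
        return format
    return "json" if str(path).lower().endswith(".json") else "csv"


def read_records(
    path: PathLike,
    format: Optional[str] = None,
    ratio_as_percent: bool = False,
) -> list[PFTRecord]:
    """Read PFT records from CSV (canonical) or JSON.

    ``ratio_as_percent`` accepts FEV1/FVC given as a percent (70 -> 0.70) for
    sources that store the ratio that way. Duplicate record ids raise a
    validation error; field invariants are enforced per record.
    """
    fmt = _infer_format(path, format)
    rows: list[dict]
    if fmt == "json":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise ParseError(f"{path}: JSON records must be a list of objects")
        rows = [dict(obj) for obj in data]
    elif fmt == "csv":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or reader.fieldnames[0] != "record_id":
                raise ParseError(
                    f"{path}: expected header starting with 'record_id', got {reader.fieldnames}"
                )
            unknown = set(reader.fieldnames) - set(RECORD_FIELDS)
            if unknown:
                raise ParseError(f"{path}: unknown columns {sorted(unknown)}")
            rows = list(reader)
    else:
        raise ValidationError(f"unknown records format {fmt!r}")

    records: list[PFTRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=1):
        rid = str(row.get("record_id") or "").strip()
        if not rid:
            raise ParseError(f"row {i}: missing record_id")
        if rid in seen:
            raise ValidationError(f"duplicate record_id {rid!r}")
        seen.add(rid)
        values: dict = {}
        for fld in _NUMERIC_FIELDS:
            raw = row.get(fld)
            if isinstance(raw, (int, float)):
                values[fld] = float(raw)
            else:
                values[fld] = _parse_cell(raw, i, fld)
        if ratio_as_percent and values["fev1_fvc_ratio"] is not None:
            values["fev1_fvc_ratio"] /= 100.0
        text = row.get("clinician_text")
        if text is not None:
            text = str(text)
            if text == "":
                text = None
        records.append(PFTRecord(record_id=rid, clinician_text=text, **values))
    return records


def write_records(records: Sequence[PFTRecord], path: PathLike) -> None:
    """Write records to canonical CSV (``repr`` floats, empty cell = absent)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_FIELDS)
        for rec in records:
            writer.writerow(
                [
                    rec.record_id,
                    *("" if getattr(rec, f) is None else repr(getattr(rec, f)) for f in _NUMERIC_FIELDS),
                    rec.clinician_text if rec.clinician_text is not None else "",
                ]
            )


def read_curves(
    path: PathLike,
    format: Optional[str] = None,
    min_points: int = MIN_CURVE_POINTS,
) -> dict[str, FlowVolumeCurve]:
    """Read flow-volume curves, grouped per record id and sorted by volume.

    Duplicate (id, volume) pairs and any other invariant violation raise;
    sorting is the only silent canonicalization.
    """
    fmt = _infer_format(path, format)
    groups: dict[str, list[tuple[float, float]]] = {}
    if fmt == "json":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, dict):
            raise ParseError(f"{path}: JSON curves must map record_id to point lists")
        for rid, pts in data.items():
            groups[str(rid)] = [(float(v), float(f)) for v, f in pts]
    elif fmt == "csv":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or set(CURVE_FIELDS) - set(reader.fieldnames):
                raise ParseError(f"{path}: expected header {','.join(CURVE_FIELDS)}")
            for i, row in enumerate(reader, start=1):
                rid = str(row["record_id"]).strip()
                if not rid:
                    raise ParseError(f"row {i}: missing record_id")
                v = _parse_cell(row["volume_expired_l"], i, "volume_expired_l")
                f = _parse_cell(row["flow_l_s"], i, "flow_l_s")
                if v is None or f is None:
                    raise ParseError(f"row {i}: empty volume or flow cell")
                groups.setdefault(rid, []).append((v, f))
    else:
        raise ValidationError(f"unknown curves format {fmt!r}")

    curves: dict[str, FlowVolumeCurve] = {}
    for rid, pts in groups.items():
        pts.sort(key=lambda p: p[0])
        vols = np.array([p[0] for p in pts])
        if np.any(np.diff(vols) == 0):
            raise ValidationError(f"curve {rid!r}: duplicate volume sample")
        curves[rid] = FlowVolumeCurve.from_points(rid, pts, min_points=min_points)
    return curves


def write_curves(curves: dict[str, FlowVolumeCurve], path: PathLike) -> None:
    """Write curves to the canonical long-format CSV, sorted by record id."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CURVE_FIELDS)
        for rid in sorted(curves):
            curve = curves[rid]
            for v, f in zip(curve.volume, curve.flow):
                writer.writerow([rid, repr(float(v)), repr(float(f))])
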