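"""Optional adapter extracting a PFT record, curve and impression from a vendor report PDF.

Vendor report layouts differ, so everything dialect-specific lives in an
:class:`PdfAdapterConfig` (loadable from YAML/JSON): the label-to-field
mapping for the numeric table, the heading that introduces the clinician
impression, and a two-reference-tick affine calibration per axis for
converting the flow-volume panel's vector line segments into physical
(volume, flow) points.

The PDF layer itself is handled by ``pdfplumber``, imported lazily: this
adapter is an optional entry point and the rest of the package never touches
it. The pure parsing/calibration helpers below operate on pre-extracted text
lines and point lists and are usable (and tested) without any PDF stack.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .errors import MissingDependencyError, ParseError, UnsupportedDocumentError, ValidationError
from .types import FlowVolumeCurve, PFTRecord

__all__ = [
    "AxisCalibration",
    "PdfAdapterConfig",
    "parse_numeric_fields",
    "parse_impression",
    "calibrate_points",
    "extract_pdf_report",
]

_NUMBER_RE = re.compile(r"[-+]?\d+(?:\.\d+)?")

_DEFAULT_FIELD_LABELS = {
    "fev1_fvc_ratio": ["FEV1/FVC"],
    "tlc_pct_pred": ["TLC % Pred", "TLC %Pred"],
    "dlco_pct_pred": ["DLCO % Pred", "DLCO %Pred"],
}


@dataclass(frozen=True)
class AxisCalibration:
    """Two (device coordinate, data value) reference ticks defining an affine axis map."""

    ticks: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        (d0, _), (d1, _) = self.ticks
        if d0 == d1:
            raise ValidationError("axis calibration ticks must have distinct device coordinates")

    def to_data(self, device: float) -> float:
        (d0, x0), (d1, x1) = self.ticks
        return x0 + (device - d0) * (x1 - x0) / (d1 - d0)


@dataclass(frozen=True)
class PdfAdapterConfig:
    """Dialect-specific mapping from a vendor report to canonical fields."""

    field_labels: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_FIELD_LABELS.items()}
    )
    impression_heading: str = "Impression"
    ratio_as_percent: bool = False
    volume_axis: Optional[AxisCalibration] = None
    flow_axis: Optional[AxisCalibration] = None

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PdfAdapterConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        axes = {}
        for key in ("volume_axis", "flow_axis"):
            if data.get(key):
                axes[key] = AxisCalibration(tuple(tuple(t) for t in data[key]))
        return cls(
            field_labels={k: list(v) for k, v in data.get("field_labels", _DEFAULT_FIELD_LABELS).items()},
            impression_heading=data.get("impression_heading", "Impression"),
            ratio_as_percent=bool(data.get("ratio_as_percent", False)),
            **axes,
        )


def parse_numeric_fields(lines: Sequence[str], cfg: PdfAdapterConfig) -> dict[str, float]:
    """Map labelled report lines to numeric fields.

    For each configured label, the first number following the label on its
    line is taken; the first matching label per field wins.
    """
    out: dict[str, float] = {}
    for fld, labels in cfg.field_labels.items():
        for label in labels:
            if fld in out:
                break
            for line in lines:
                pos = line.find(label)
                if pos < 0:
                    continue
                m = _NUMBER_RE.search(line, pos + len(label))
                if not m:
                    raise ParseError(f"label {label!r} found but no number follows on its line")
                value = float(m.group())
                if fld == "fev1_fvc_ratio" and cfg.ratio_as_percent:
                    value /= 100.0
                out[fld] = value
                break
    return out


def parse_impression(lines: Sequence[str], cfg: PdfAdapterConfig) -> Optional[str]:
    """Verbatim text from the impression heading to the end of the block."""
    for i, line in enumerate(lines):
        if cfg.impression_heading.lower() in line.lower():
            tail = line.split(":", 1)[1].strip() if ":" in line else ""
            rest = [ln.strip() for ln in lines[i + 1 :] if ln.strip()]
            text = " ".join(([tail] if tail else []) + rest).strip()
            return text or None
    return None


def calibrate_points(
    device_points: Sequence[tuple[float, float]],
    cfg: PdfAdapterConfig,
    record_id: str,
    min_points: int = 10,
) -> FlowVolumeCurve:
    """Convert device-space FVL polyline points to a physical curve.

    Points are mapped through both axis calibrations, sorted by volume, and
    shifted so the first sample sits at volume 0.
    """
    if cfg.volume_axis is None or cfg.flow_axis is None:
        raise ValidationError("both volume_axis and flow_axis calibrations are required")
    pts = sorted(
        (cfg.volume_axis.to_data(x), cfg.flow_axis.to_data(y)) for x, y in device_points
    )
    v0 = pts[0][0]
    return FlowVolumeCurve.from_points(
        record_id, [(v - v0, f) for v, f in pts], min_points=min_points
    )


def extract_pdf_report(
    path: Union[str, Path],
    cfg: Optional[PdfAdapterConfig] = None,
    record_id: Optional[str] = None,
) -> tuple[PFTRecord, Optional[FlowVolumeCurve], Optional[str]]:
    """Extract (record, curve-or-None, impression text) from one report PDF.

    Requires the optional ``pdfplumber`` dependency. Reports without a
    machine-readable text layer (image-only scans) raise
    :class:`UnsupportedDocumentError`. If the flow-volume panel cannot be
    calibrated the curve is returned as ``None`` while numeric fields are
    still extracted.
    """
    try:
        import pdfplumber
    except ImportError as exc:  # pragma: no cover - exercised via the error path
        raise MissingDependencyError(
            "PDF extraction requires the optional dependency 'pdfplumber' "
            "(install with: pip install pftinterp[pdf])"
        ) from exc

    cfg = cfg or PdfAdapterConfig()
    rid = record_id or Path(path).stem
    with pdfplumber.open(path) as pdf:
        text = "\n".join(filter(None, (page.extract_text() for page in pdf.pages)))
        if not text.strip():
            raise UnsupportedDocumentError(
                f"{path}: no machine-readable text layer (image-only scan?)"
            )
        lines = text.splitlines()
        fields = parse_numeric_fields(lines, cfg)
        impression = parse_impression(lines, cfg)
        curve: Optional[FlowVolumeCurve] = None
        if cfg.volume_axis is not None and cfg.flow_axis is not None:
            device_pts = [
                pt
                for page in pdf.pages
                for ln in page.lines
                for pt in ((ln["x0"], ln["y0"]), (ln["x1"], ln["y1"]))
            ]
            if device_pts:
                try:
                    curve = calibrate_points(device_pts, cfg, rid)
                except (ValidationError, ParseError):
                    curve = None
    record = PFTRecord(record_id=rid, clinician_text=impression, **fields)
    return record, curve, impression
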