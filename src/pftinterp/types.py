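"""Core domain containers: one PFT's numeric measurements and its expiratory flow-volume limb.

Conventions
-----------
* FEV1/FVC is stored as a dimensionless *fraction* (0.70, not 70).
* TLC and DLCO are stored as percent-of-predicted (83.3 means 83.3 %pred).
* Curve volumes are liters expired since the start of forced expiration, so the
  expiratory limb runs left to right from volume 0 and flow falls to the volume
  axis at the expiratory vital capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

#: default minimum number of digitized samples a curve must carry to be usable
#: for segment regression downstream
MIN_CURVE_POINTS = 10


@dataclass(frozen=True)
class PFTRecord:
    """Numeric measurements of a single pulmonary function test.

    Any measurement may be absent (``None``); absence is preserved, never
    coerced to zero, because a missing component downstream means
    "not assessable", not "normal".
    """

    record_id: str
    fev1_fvc_ratio: Optional[float] = None
    tlc_pct_pred: Optional[float] = None
    dlco_pct_pred: Optional[float] = None
    clinician_text: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValidationError("record_id must be a non-empty string")
        r = self.fev1_fvc_ratio
        if r is not None:
            if not math.isfinite(r) or not (0.0 <= r <= 1.0):
                raise ValidationError(
                    f"record {self.record_id!r}: fev1_fvc_ratio must lie in [0, 1], got {r}"
                )
        for name in ("tlc_pct_pred", "dlco_pct_pred"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(
                    f"record {self.record_id!r}: {name} must be finite and >= 0, got {v}"
                )


@dataclass(frozen=True)
class FlowVolumeCurve:
    """Ordered (volume expired, flow) samples of one expiratory limb.

    Parameters
    ----------
    record_id : str
        Identifier linking the curve to its :class:`PFTRecord`.
    volume : array of float
        Liters expired since start of expiration; strictly increasing, first
        sample at 0.
    flow : array of float
        Flow in L/s at each sample; finite, may dip below zero at the very end
        of the effort.
    min_points : int
        Minimum number of samples enforced at construction.
    """

    record_id: str
    volume: np.ndarray
    flow: np.ndarray
    min_points: int = field(default=MIN_CURVE_POINTS, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.volume, dtype=float)
        f = np.asarray(self.flow, dtype=float)
        object.__setattr__(self, "volume", v)
        object.__setattr__(self, "flow", f)
        if not self.record_id:
            raise ValidationError("curve record_id must be non-empty")
        if v.ndim != 1 or f.ndim != 1 or v.shape != f.shape:
            raise ValidationError(
                f"curve {self.record_id!r}: volume and flow must be 1-D arrays of equal length"
            )
        if len(v) < self.min_points:
            raise ValidationError(
                f"curve {self.record_id!r}: {len(v)} points, minimum is {self.min_points}"
            )
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(f))):
            raise ValidationError(f"curve {self.record_id!r}: non-finite sample")
        if abs(v[0]) > 1e-9:
            raise ValidationError(
                f"curve {self.record_id!r}: first sample must be at volume 0, got {v[0]}"
            )
        if np.any(np.diff(v) <= 0):
            raise ValidationError(
                f"curve {self.record_id!r}: volume must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.volume)

    @property
    def points(self) -> list[tuple[float, float]]:
        """Samples as a list of (volume, flow) tuples."""
        return list(zip(self.volume.tolist(), self.flow.tolist()))

    @classmethod
    def from_points(
        cls,
        record_id: str,
        points: Sequence[tuple[float, float]],
        min_points: int = MIN_CURVE_POINTS,
    ) -> "FlowVolumeCurve":
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("points must be a sequence of (volume, flow) pairs")
        return cls(record_id, pts[:, 0], pts[:, 1], min_points=min_points)
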