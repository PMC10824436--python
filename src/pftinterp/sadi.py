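"""Small Airway Disease Index (SADI) from the expiratory flow-volume limb.

SADI quantifies late-expiratory flattening of the flow-volume loop as the
angle between two least-squares lines fitted to the descending limb:

* segment A->B, from the peak expiratory flow (A) down to the point at 75 %
  of the expiratory vital capacity (B), roughly where small airways begin to
  dominate resistance, and
* segment B->C, from B to where the limb meets the volume axis (C).

A straight descent gives 180 degrees; the more the tail of the limb flattens
(concave limb, small-airway disease), the smaller the angle. A cohort lower
limit of normal (LLN) is calibrated as mean - 1.64 x SD of the angles in
tests without obstruction; an angle below the LLN in a non-obstructed test
flags small airway dysfunction.

Slopes mix L/s and L, so the angle depends on the plotting aspect ratio; the
``aspect`` parameter (L/s per L, default 1.0) fixes that convention and is
carried with every result. The angle is invariant under uniform rescaling of
both axes and under volume translation, but not under changes of ``aspect``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateCurveError, InsufficientDataError, ValidationError
from .interpreter import InterpretationResult, Obstruction, SmallAirway
from .types import FlowVolumeCurve

__all__ = [
    "SADILandmarks",
    "SADIResult",
    "CohortNorm",
    "locate_landmarks",
    "compute_sadi",
    "derive_lln",
    "flag_small_airway",
]

#: fraction of the expiratory vital capacity at which landmark B sits
B_VC_FRACTION = 0.75

#: one-sided 5th-percentile multiplier under normality
DEFAULT_LLN_MULTIPLIER = 1.64


@dataclass(frozen=True)
class SADILandmarks:
    """The three anchor points of the descending limb.

    ``a`` is the (volume, flow) sample at peak expiratory flow, ``b`` the
    interpolated point at 75 % of the expiratory vital capacity, ``c`` the
    (interpolated) zero-flow intercept. Volumes satisfy
    vol(a) <= vol(b) < vol(c) and flow(c) == 0.
    """

    a: tuple[float, float]
    b: tuple[float, float]
    c: tuple[float, float]

    @property
    def expiratory_vc(self) -> float:
        """Expiratory vital capacity measured on the curve (volume at C)."""
        return self.c[0]


@dataclass(frozen=True)
class SADIResult:
    record_id: str
    angle_deg: float
    slope_ab: float
    slope_bc: float
    n_ab: int
    n_bc: int
    landmarks: SADILandmarks
    aspect: float = 1.0


@dataclass(frozen=True)
class CohortNorm:
    """Population mean/SD of SADI and the derived lower limit of normal."""

    n: int
    mean: float
    sd: float
    multiplier: float = DEFAULT_LLN_MULTIPLIER
    lln: float = None  # type: ignore[assignment]  # derived in __post_init__ when omitted

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd}")
        if self.lln is None:
            object.__setattr__(self, "lln", self.mean - self.multiplier * self.sd)

    @classmethod
    def from_moments(
        cls, mean: float, sd: float, multiplier: float = DEFAULT_LLN_MULTIPLIER, n: int = 0
    ) -> "CohortNorm":
        """Norm from published cohort moments rather than raw angles."""
        return cls(n=n, mean=mean, sd=sd, multiplier=multiplier)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": round(self.mean, 1),
            "sd": round(self.sd, 1),
            "multiplier": self.multiplier,
            "lln": round(self.lln, 1),
        }


def locate_landmarks(curve: FlowVolumeCurve) -> SADILandmarks:
    """Find peak flow (A), the 75 %-VC point (B) and the zero-flow intercept (C).

    A is the first sample attaining the maximum flow. C is the first zero-flow
    crossing after A, linearly interpolated between bracketing samples; if the
    flow never reaches zero the last sample closes the limb. B is the linearly
    interpolated flow at 0.75 x VC, where VC is the volume at C.

    Raises
    ------
    DegenerateCurveError
        If the peak sits on the last sample (no descending limb) or B does
        not fall strictly after A.
    """
    v, f = curve.volume, curve.flow
    i_a = int(np.argmax(f))  # first max on ties
    if i_a == len(v) - 1:
        raise DegenerateCurveError(
            f"curve {curve.record_id!r}: peak flow at the last sample, no descending limb"
        )
    a = (float(v[i_a]), float(f[i_a]))

    # first zero crossing strictly after the peak
    v_c: Optional[float] = None
    for i in range(i_a + 1, len(v)):
        if f[i] <= 0.0:
            if f[i] == 0.0:
                v_c = float(v[i])
            else:
                # interpolate between the last positive sample and this one
                f0, f1 = float(f[i - 1]), float(f[i])
                v0, v1 = float(v[i - 1]), float(v[i])
                v_c = v0 + (v1 - v0) * f0 / (f0 - f1)
            break
    if v_c is None:
        v_c = float(v[-1])
    c = (v_c, 0.0)

    v_b = B_VC_FRACTION * v_c
    if v_b <= a[0]:
        raise DegenerateCurveError(
            f"curve {curve.record_id!r}: 75 %-VC point (volume {v_b:.3f} L) does not fall "
            f"after the peak (volume {a[0]:.3f} L)"
        )
    f_b = float(np.interp(v_b, v, f))
    return SADILandmarks(a=a, b=(v_b, f_b), c=c)


def _fit_slope(v: np.ndarray, f: np.ndarray) -> float:
    # OLS slope of flow on volume; >= 2 distinct volumes guaranteed upstream
    vc = v - v.mean()
    return float(np.dot(vc, f - f.mean()) / np.dot(vc, vc))


def compute_sadi(
    curve: FlowVolumeCurve,
    aspect: float = 1.0,
    min_segment_points: int = 3,
) -> SADIResult:
    """Compute the SADI angle for one curve.

    Ordinary least-squares lines are fitted to the samples of each segment;
    the interpolated landmarks B (both segments) and C (segment B->C) are
    appended to the fitted point sets. Slopes are divided by ``aspect``
    before the angle ``180 - |atan(s_ab) - atan(s_bc)|`` (degrees) is taken,
    so the angle matches what an interpreter would see on a plot drawn with
    that aspect ratio.

    Raises
    ------
    InsufficientDataError
        If either segment carries fewer than ``min_segment_points`` points
        (interpolated landmarks included).
    """
    if not (math.isfinite(aspect) and aspect > 0):
        raise ValidationError(f"aspect must be finite and positive, got {aspect}")
    lm = locate_landmarks(curve)
    v, f = curve.volume, curve.flow
    (v_a, _), (v_b, f_b), (v_c, _) = lm.a, lm.b, lm.c

    sel_ab = (v >= v_a) & (v <= v_b)
    ab_v = v[sel_ab].tolist()
    ab_f = f[sel_ab].tolist()
    if not ab_v or ab_v[-1] < v_b:
        ab_v.append(v_b)
        ab_f.append(f_b)

    sel_bc = (v >= v_b) & (v <= v_c)
    bc_v = v[sel_bc].tolist()
    bc_f = f[sel_bc].tolist()
    if not bc_v or bc_v[0] > v_b:
        bc_v.insert(0, v_b)
        bc_f.insert(0, f_b)
    if bc_v[-1] < v_c:
        bc_v.append(v_c)
        bc_f.append(0.0)

    if len(ab_v) < min_segment_points:
        raise InsufficientDataError(
            f"curve {curve.record_id!r}: segment A-B has {len(ab_v)} points, "
            f"minimum is {min_segment_points}"
        )
    if len(bc_v) < min_segment_points:
        raise InsufficientDataError(
            f"curve {curve.record_id!r}: segment B-C has {len(bc_v)} points, "
            f"minimum is {min_segment_points}"
        )

    slope_ab = _fit_slope(np.asarray(ab_v), np.asarray(ab_f)) / aspect
    slope_bc = _fit_slope(np.asarray(bc_v), np.asarray(bc_f)) / aspect
    angle = 180.0 - abs(math.degrees(math.atan(slope_ab)) - math.degrees(math.atan(slope_bc)))
    return SADIResult(
        record_id=curve.record_id,
        angle_deg=angle,
        slope_ab=slope_ab,
        slope_bc=slope_bc,
        n_ab=len(ab_v),
        n_bc=len(bc_v),
        landmarks=lm,
        aspect=aspect,
    )


def derive_lln(
    values: Sequence[float], multiplier: float = DEFAULT_LLN_MULTIPLIER
) -> CohortNorm:
    """Cohort norm (mean, SD, LLN = mean - multiplier x SD) from raw angles.

    SD is the sample standard deviation (ddof=1). At least two finite values
    are required.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"need >= 2 values to derive an LLN, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite value in SADI cohort")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return CohortNorm(n=int(arr.size), mean=mean, sd=sd, multiplier=multiplier)


def flag_small_airway(
    result: InterpretationResult,
    sadi: Optional[SADIResult],
    norm: CohortNorm,
) -> SmallAirway:
    """Small-airway category for one interpreted record.

    The flag only applies to tests *without* obstruction: flagged iff the
    angle falls strictly below the cohort LLN; not assessable when the test
    is obstructed (or obstruction itself was not assessable) or no curve was
    available.
    """
    if result.obstruction is not Obstruction.NOT_OBSTRUCTED or sadi is None:
        return SmallAirway.NOT_ASSESSABLE
    if sadi.angle_deg < norm.lln:
        return SmallAirway.FLAGGED
    return SmallAirway.NOT_FLAGGED
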