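"""Rule-based categorical interpretation of a PFT record.

The decision rules mirror routine clinical practice: obstruction when
FEV1/FVC < 0.70, restriction when TLC < 80 %pred, and abnormal gas transfer
when DLCO < 80 %pred (reduced) or > 120 %pred (elevated). All cutoffs are
strict; equality with a cutoff is read as normal. A missing measurement makes
the corresponding axis *not assessable* rather than normal, so that missing
interpretations can be tallied separately downstream.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ValidationError
from .types import PFTRecord

__all__ = [
    "Obstruction",
    "Restriction",
    "Dlco",
    "SmallAirway",
    "RuleConfig",
    "DLCO_WIDE",
    "InterpretationResult",
    "classify_obstruction",
    "classify_restriction",
    "classify_dlco",
    "interpret_record",
]


class Obstruction(str, enum.Enum):
    OBSTRUCTED = "obstructed"
    NOT_OBSTRUCTED = "not_obstructed"
    NOT_ASSESSABLE = "not_assessable"


class Restriction(str, enum.Enum):
    RESTRICTED = "restricted"
    NOT_RESTRICTED = "not_restricted"
    NOT_ASSESSABLE = "not_assessable"


class Dlco(str, enum.Enum):
    REDUCED = "reduced"
    NORMAL = "normal"
    ELEVATED = "elevated"
    NOT_ASSESSABLE = "not_assessable"


class SmallAirway(str, enum.Enum):
    FLAGGED = "flagged"
    NOT_FLAGGED = "not_flagged"
    NOT_ASSESSABLE = "not_assessable"


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds applied by the classifiers.

    ``obstruction_ratio_cutoff`` is a fraction; the three others are
    percent-of-predicted. The ``dlco_wide`` preset (70-130 %pred) matches a
    wider normal range some interpreters use for gas transfer.
    """

    obstruction_ratio_cutoff: float = 0.70
    restriction_tlc_cutoff: float = 80.0
    dlco_low: float = 80.0
    dlco_high: float = 120.0

    def __post_init__(self) -> None:
        if not (0.0 < self.obstruction_ratio_cutoff < 1.0):
            raise ValidationError(
                f"obstruction_ratio_cutoff must lie in (0, 1), got {self.obstruction_ratio_cutoff}"
            )
        for name in ("restriction_tlc_cutoff", "dlco_low", "dlco_high"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and positive, got {v}")
        if not self.dlco_low < self.dlco_high:
            raise ValidationError(
                f"dlco_low ({self.dlco_low}) must be below dlco_high ({self.dlco_high})"
            )


#: preset with the wider 70-130 %pred DLCO normal range
DLCO_WIDE = RuleConfig(dlco_low=70.0, dlco_high=130.0)


@dataclass(frozen=True)
class InterpretationResult:
    """Categorical interpretation of one record, with the config that produced it."""

    record_id: str
    obstruction: Obstruction
    restriction: Restriction
    dlco: Dlco
    small_airway: SmallAirway = SmallAirway.NOT_ASSESSABLE
    applied_config: RuleConfig = field(default_factory=RuleConfig)

    def with_small_airway(self, category: SmallAirway) -> "InterpretationResult":
        return replace(self, small_airway=category)


def classify_obstruction(ratio: Optional[float], cfg: RuleConfig = RuleConfig()) -> Obstruction:
    """Obstructed iff FEV1/FVC < cutoff (strict); missing ratio is not assessable."""
    if ratio is None:
        return Obstruction.NOT_ASSESSABLE
    if not (math.isfinite(ratio) and 0.0 <= ratio <= 1.0):
        raise ValidationError(f"fev1_fvc_ratio must lie in [0, 1], got {ratio}")
    if ratio < cfg.obstruction_ratio_cutoff:
        return Obstruction.OBSTRUCTED
    return Obstruction.NOT_OBSTRUCTED


def classify_restriction(tlc_pct: Optional[float], cfg: RuleConfig = RuleConfig()) -> Restriction:
    """Restricted iff TLC %pred < cutoff (strict); missing TLC is not assessable."""
    if tlc_pct is None:
        return Restriction.NOT_ASSESSABLE
    if not (math.isfinite(tlc_pct) and tlc_pct >= 0):
        raise ValidationError(f"tlc_pct_pred must be finite and >= 0, got {tlc_pct}")
    if tlc_pct < cfg.restriction_tlc_cutoff:
        return Restriction.RESTRICTED
    return Restriction.NOT_RESTRICTED


def classify_dlco(dlco_pct: Optional[float], cfg: RuleConfig = RuleConfig()) -> Dlco:
    """Reduced below the low cutoff, elevated above the high cutoff, normal in between.

    Both bounds are inclusive on the normal side (DLCO of exactly 80 or
    120 %pred is normal under the default config).
    """
    if dlco_pct is None:
        return Dlco.NOT_ASSESSABLE
    if not (math.isfinite(dlco_pct) and dlco_pct >= 0):
        raise ValidationError(f"dlco_pct_pred must be finite and >= 0, got {dlco_pct}")
    if dlco_pct < cfg.dlco_low:
        return Dlco.REDUCED
    if dlco_pct > cfg.dlco_high:
        return Dlco.ELEVATED
    return Dlco.NORMAL


def interpret_record(rec: PFTRecord, cfg: RuleConfig = RuleConfig()) -> InterpretationResult:
    """Apply all three rules to one record.

    The small-airway axis is initialized *not assessable*; it is populated by
    :func:`pftinterp.sadi.flag_small_airway` once a curve and a cohort norm
    are available.
    """
    return InterpretationResult(
        record_id=rec.record_id,
        obstruction=classify_obstruction(rec.fev1_fvc_ratio, cfg),
        restriction=classify_restriction(rec.tlc_pct_pred, cfg),
        dlco=classify_dlco(rec.dlco_pct_pred, cfg),
        applied_config=cfg,
    )
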