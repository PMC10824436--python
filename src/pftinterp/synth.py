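"""Seeded generators: flow-volume curves, PFT cohorts with known truth, clinician texts.

The curve family is a deliberately simple two-phase shape with one concavity
knob, not a physiological forced-expiration model: flow rises linearly to the
peak at a fixed fraction of vital capacity, then decays as
``pef * ((vc - v) / (vc - v_peak)) ** gamma``. ``gamma = 1`` is a straight
descent (SADI angle exactly 180 degrees); larger gamma produces the
late-expiratory flattening seen in small-airway disease, monotonically
shrinking the angle. The uniform sampling grid always contains the exact peak
point so the gamma = 1 family stays exactly piecewise-linear.

Cohorts draw per-subject abnormality truths by prevalence, numeric values
strictly separated from the rule cutoffs (so the interpreter recovers truth
exactly), and target SADI angles from a clipped normal law inverted through
an empirically tabulated gamma-to-angle map. Clinician impressions are
templated sentences per category, with seeded label flips (``error_rate``)
and whole-text blanking (``missing_rate``). One global seed fans out to
per-subject substreams, so cohorts are reproducible under subsetting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from . import sadi as _sadi
from .errors import ValidationError
from .types import FlowVolumeCurve, PFTRecord

__all__ = [
    "CurveParams",
    "CohortParams",
    "Cohort",
    "generate_curve",
    "generate_cohort",
    "generate_clinician_text",
    "gamma_for_angle",
    "angle_for_gamma",
]


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one synthetic expiratory limb.

    ``vc`` liters, ``pef`` L/s, peak at ``v_peak_frac * vc``; ``gamma >= 1``
    controls late-expiratory concavity; Gaussian flow noise of ``noise_sd``
    L/s is added to the descending samples when positive.
    """

    vc: float = 4.0
    pef: float = 8.0
    v_peak_frac: float = 0.1
    gamma: float = 1.0
    n_points: int = 50
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.vc > 0 and self.pef > 0):
            raise ValidationError("vc and pef must be positive")
        if not (0 < self.v_peak_frac <= 0.3):
            raise ValidationError(f"v_peak_frac must lie in (0, 0.3], got {self.v_peak_frac}")
        if self.gamma < 1:
            raise ValidationError(f"gamma must be >= 1, got {self.gamma}")
        if self.n_points < 20:
            raise ValidationError(f"n_points must be >= 20, got {self.n_points}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def _flow_model(v: np.ndarray, vc: float, pef: float, v_peak: float, gamma: float) -> np.ndarray:
    rising = v <= v_peak
    f = np.empty_like(v)
    f[rising] = pef * v[rising] / v_peak
    f[~rising] = pef * ((vc - v[~rising]) / (vc - v_peak)) ** gamma
    return f


def generate_curve(p: CurveParams, record_id: str = "synthetic") -> FlowVolumeCurve:
    """Sample one curve on a uniform volume grid (exact peak point inserted)."""
    v_peak = p.v_peak_frac * p.vc
    v = np.linspace(0.0, p.vc, p.n_points)
    if not np.any(np.isclose(v, v_peak, rtol=0, atol=1e-12)):
        v = np.sort(np.append(v, v_peak))
    f = _flow_model(v, p.vc, p.pef, v_peak, p.gamma)
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        noise = rng.normal(0.0, p.noise_sd, size=len(v))
        noise[0] = 0.0  # keep the origin anchored
        f = f + noise
    f[-1] = 0.0  # limb closes on the volume axis
    return FlowVolumeCurve(record_id=record_id, volume=v, flow=f)


# ---------------------------------------------------------------------------
# gamma <-> angle mapping (shape-invariant: fixed pef/vc ratio, scale-free)
# ---------------------------------------------------------------------------

_REF_SHAPE = dict(vc=4.0, pef=8.0, v_peak_frac=0.1, n_points=50)
#: the gamma-to-angle map is strictly decreasing on [1, 4] for the reference
#: shape; beyond that the flat tail starts to dominate the A-B fit as well and
#: the map turns around, so inversion is restricted to this range
_GAMMA_GRID_MAX = 4.0


@lru_cache(maxsize=8)
def _gamma_angle_table(
    vc: float, pef: float, v_peak_frac: float, n_points: int
) -> tuple[np.ndarray, np.ndarray]:
    gammas = np.concatenate([np.linspace(1.0, 3.0, 81), np.linspace(3.05, _GAMMA_GRID_MAX, 40)])
    angles = np.array(
        [
            _sadi.compute_sadi(
                generate_curve(
                    CurveParams(vc=vc, pef=pef, v_peak_frac=v_peak_frac, gamma=g, n_points=n_points)
                )
            ).angle_deg
            for g in gammas
        ]
    )
    return gammas, angles


def angle_for_gamma(gamma: float, **shape) -> float:
    """Noise-free SADI angle of the reference-shape curve at this gamma."""
    p = {**_REF_SHAPE, **shape}
    return _sadi.compute_sadi(generate_curve(CurveParams(gamma=gamma, **p))).angle_deg


def gamma_for_angle(angle_deg: float, **shape) -> float:
    """Invert the (monotone decreasing) gamma-to-angle map by interpolation.

    Angles above 180 or below the grid's minimum achievable angle are clipped
    to the achievable range.
    """
    p = {**_REF_SHAPE, **shape}
    gammas, angles = _gamma_angle_table(p["vc"], p["pef"], p["v_peak_frac"], p["n_points"])
    # angles decrease with gamma; np.interp needs increasing x
    return float(np.interp(angle_deg, angles[::-1], gammas[::-1]))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Study-condition knobs for a synthetic cohort.

    Prevalences are marginal truth rates; ``small_airway_prev``, when given,
    forces that truth rate among non-obstructed subjects (otherwise the
    small-airway truth arises naturally from the angle distribution, about
    5 % under the default normal law). ``sadi_mean``/``sadi_sd`` are the
    target angle moments (degrees) of the non-obstructed population;
    ``clinician_error_rate`` flips individual stated labels and
    ``clinician_missing_rate`` blanks whole impressions.
    """

    n: int = 100
    obstruction_prev: float = 0.0
    restriction_prev: float = 0.0
    dlco_abnormal_prev: float = 0.0
    small_airway_prev: Optional[float] = None
    sadi_mean: float = 156.5
    sadi_sd: float = 16.9
    clinician_error_rate: float = 0.0
    clinician_missing_rate: float = 0.0
    lln_multiplier: float = _sadi.DEFAULT_LLN_MULTIPLIER
    curve_n_points: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        rates = {
            "obstruction_prev": self.obstruction_prev,
            "restriction_prev": self.restriction_prev,
            "dlco_abnormal_prev": self.dlco_abnormal_prev,
            "clinician_error_rate": self.clinician_error_rate,
            "clinician_missing_rate": self.clinician_missing_rate,
        }
        if self.small_airway_prev is not None:
            rates["small_airway_prev"] = self.small_airway_prev
        for name, r in rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {r}")
        if self.sadi_sd < 0:
            raise ValidationError("sadi_sd must be >= 0")

    @property
    def nominal_lln(self) -> float:
        return self.sadi_mean - self.lln_multiplier * self.sadi_sd


@dataclass(frozen=True)
class Cohort:
    """A generated cohort: records, curves keyed by record id, and the truth table.

    ``truth`` maps record_id to a dict with boolean truths per category
    (``small_airway`` is None for obstructed subjects, where the flag does
    not apply) plus the realized SADI angle.
    """

    records: list[PFTRecord]
    curves: dict[str, FlowVolumeCurve]
    truth: dict[str, dict]
    params: CohortParams = field(compare=False, default_factory=CohortParams)


def _subject_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))


def _draw_angle_target(rng: np.random.Generator, p: CohortParams, positive: Optional[bool]) -> float:
    lo = angle_for_gamma(_GAMMA_GRID_MAX) + 0.5
    if positive is None:
        raw = rng.normal(p.sadi_mean, p.sadi_sd)
        return float(np.clip(raw, lo, 180.0))
    # forced truth: rejection-sample the matching side of the nominal LLN,
    # with a 1-degree guard band so mapping error cannot flip the truth
    lln = p.nominal_lln
    for _ in range(1000):
        raw = rng.normal(p.sadi_mean, p.sadi_sd)
        if positive and lo <= raw <= lln - 1.0:
            return float(raw)
        if not positive and lln + 1.0 <= raw:
            return float(min(raw, 180.0))
    # prevalence target unreachable by rejection; fall back to the band edge
    return lln - 5.0 if positive else min(lln + 5.0, 180.0)


def generate_cohort(p: CohortParams) -> Cohort:
    """Generate records, curves and truth labels for ``p.n`` subjects.

    The small-airway truth is taken from the *computed* SADI of the generated
    curve against the nominal LLN (mean - multiplier x SD of the requested
    angle law), so recovery by the analysis pipeline is exact by construction.
    """
    records: list[PFTRecord] = []
    curves: dict[str, FlowVolumeCurve] = {}
    truth: dict[str, dict] = {}
    lln = p.nominal_lln
    for i in range(p.n):
        rng = _subject_rng(p.seed, i)
        rid = f"S{i:05d}"

        obstructed = bool(rng.random() < p.obstruction_prev)
        restricted = bool(rng.random() < p.restriction_prev)
        dlco_abn = bool(rng.random() < p.dlco_abnormal_prev)

        ratio = float(rng.uniform(0.45, 0.66) if obstructed else rng.uniform(0.72, 0.88))
        tlc = float(rng.uniform(55.0, 76.0) if restricted else rng.uniform(84.0, 115.0))
        if dlco_abn:
            dlco = float(
                rng.uniform(40.0, 76.0) if rng.random() < 0.75 else rng.uniform(124.0, 150.0)
            )
        else:
            dlco = float(rng.uniform(85.0, 115.0))

        sa_truth_target: Optional[bool]
        if obstructed or p.small_airway_prev is None:
            sa_truth_target = None
        else:
            sa_truth_target = bool(rng.random() < p.small_airway_prev)
        target_angle = _draw_angle_target(rng, p, sa_truth_target)

        vc = float(rng.uniform(3.0, 5.5))
        # fixed pef/vc shape ratio keeps the gamma-angle map scale-exact
        curve = generate_curve(
            CurveParams(
                vc=vc,
                pef=2.0 * vc,
                gamma=gamma_for_angle(target_angle),
                n_points=p.curve_n_points,
            ),
            record_id=rid,
        )
        angle = _sadi.compute_sadi(curve).angle_deg
        small_airway = None if obstructed else bool(angle < lln)

        truths = {
            "obstruction": obstructed,
            "restriction": restricted,
            "dlco_abnormal": dlco_abn,
            "small_airway": small_airway,
            "sadi_angle_deg": angle,
        }
        text = generate_clinician_text(
            truths, p.clinician_error_rate, p.clinician_missing_rate, rng=rng
        )
        records.append(
            PFTRecord(
                record_id=rid,
                fev1_fvc_ratio=ratio,
                tlc_pct_pred=tlc,
                dlco_pct_pred=dlco,
                clinician_text=text,
            )
        )
        curves[rid] = curve
        truth[rid] = truths
    return Cohort(records=records, curves=curves, truth=truth, params=p)


_TEMPLATES = {
    "obstruction": ("Moderate obstruction.", "No obstruction."),
    "restriction": ("Mild restriction.", "No restriction."),
    "dlco_abnormal": ("Abnormal DLCO.", "No abnormal DLCO."),
    "small_airway": (
        "Late expiratory flattening suggests small airway dysfunction.",
        "No small airway dysfunction.",
    ),
}


def generate_clinician_text(
    truth: dict,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Templated impression text for one subject's truth labels.

    Each stated category contributes one affirmative or negated sentence;
    a label flips with probability ``error_rate``; with probability
    ``missing_rate`` the whole impression is blank. Categories whose truth is
    ``None`` are omitted (the clinician does not comment on them).
    """
    if not (0.0 <= error_rate <= 1.0 and 0.0 <= missing_rate <= 1.0):
        raise ValidationError("rates must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if rng.random() < missing_rate:
        return ""
    parts = []
    for cat, (yes_t, no_t) in _TEMPLATES.items():
        val = truth.get(cat)
        if val is None:
            continue
        stated = bool(val)
        if rng.random() < error_rate:
            stated = not stated
        parts.append(yes_t if stated else no_t)
    return " ".join(parts)
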