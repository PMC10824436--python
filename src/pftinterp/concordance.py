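"""Algorithm-vs-clinician agreement: 2x2 tables, Cohen's kappa, discrepancy summaries.

Each interpretation axis is binarized (obstructed vs not, restricted vs not,
abnormal DLCO — reduced *or* elevated — vs normal, small-airway flagged vs
not). Pairs where either rater is not assessable / unstated are excluded from
the 2x2 but counted, so every rate is reported with its own denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .clin_text import ClinicianLabels, Presence
from .errors import InsufficientDataError, UndefinedKappaError, ValidationError
from .interpreter import Dlco, InterpretationResult, Obstruction, Restriction, SmallAirway

__all__ = [
    "ConcordanceTable",
    "DiscrepancySummary",
    "build_table",
    "agreement_rate",
    "cohens_kappa",
    "summarize_discrepancies",
    "flag_rate",
    "binarize_algorithm",
    "binarize_clinician",
    "compare_cohort",
]

CATEGORIES = ("obstruction", "restriction", "dlco_abnormal", "small_airway")


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 agreement counts between algorithm (rows) and clinician (columns).

    ``a``: both positive, ``b``: algorithm positive / clinician negative,
    ``c``: algorithm negative / clinician positive, ``d``: both negative.
    ``excluded`` counts pairs dropped because either side was not assessable
    or unstated.
    """

    category: str
    a: int
    b: int
    c: int
    d: int
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d, self.excluded) < 0:
            raise ValidationError("table counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def p_o(self) -> float:
        """Observed agreement fraction."""
        if self.n == 0:
            raise InsufficientDataError(f"{self.category}: empty table")
        return (self.a + self.d) / self.n

    @property
    def p_e(self) -> float:
        """Chance agreement fraction from the marginals."""
        n = self.n
        if n == 0:
            raise InsufficientDataError(f"{self.category}: empty table")
        return ((self.a + self.b) * (self.a + self.c) + (self.c + self.d) * (self.b + self.d)) / n**2

    @property
    def agreement_pct(self) -> float:
        return agreement_rate(self)

    @property
    def kappa(self) -> Optional[float]:
        """Cohen's kappa, or None when undefined (degenerate marginals)."""
        try:
            return cohens_kappa(self)
        except UndefinedKappaError:
            return None

    def to_dict(self) -> dict:
        k = self.kappa
        return {
            "category": self.category,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "n": self.n,
            "excluded": self.excluded,
            "agreement_pct": self.agreement_pct,
            "kappa": None if k is None else round(k, 3),
        }


@dataclass(frozen=True)
class DiscrepancySummary:
    """Distribution of the driving measurement among discrepant tests."""

    category: str
    values: tuple[float, ...]
    window: tuple[float, float]
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    n_in_window: int
    pct_in_window: float


def build_table(
    pairs: Iterable[tuple[Optional[bool], Optional[bool]]], category: str = ""
) -> ConcordanceTable:
    """Tally (algorithm, clinician) boolean pairs into a 2x2 table.

    ``None`` on either side marks a pair as excluded (not assessable or
    unstated); excluded pairs are counted separately.
    """
    a = b = c = d = excluded = 0
    for alg, cli in pairs:
        if alg is None or cli is None:
            excluded += 1
        elif alg and cli:
            a += 1
        elif alg and not cli:
            b += 1
        elif cli:
            c += 1
        else:
            d += 1
    if a + b + c + d == 0:
        raise InsufficientDataError(f"{category or 'table'}: zero usable pairs")
    return ConcordanceTable(category=category, a=a, b=b, c=c, d=d, excluded=excluded)


def agreement_rate(table: ConcordanceTable) -> float:
    """Percent agreement, 100 x (a + d) / n, to one decimal."""
    if table.n < 1:
        raise InsufficientDataError(f"{table.category}: empty table")
    return round(100.0 * (table.a + table.d) / table.n, 1)


def cohens_kappa(table: ConcordanceTable) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    Raises :class:`UndefinedKappaError` when the marginals are degenerate
    (p_e == 1), where the statistic has no value.
    """
    if table.n < 1:
        raise InsufficientDataError(f"{table.category}: empty table")
    p_o, p_e = table.p_o, table.p_e
    if p_e >= 1.0:
        raise UndefinedKappaError(
            f"{table.category}: chance agreement is 1 (degenerate marginals); kappa undefined"
        )
    return (p_o - p_e) / (1.0 - p_e)


def summarize_discrepancies(
    values: Sequence[float], window: tuple[float, float], category: str = ""
) -> DiscrepancySummary:
    """Mean/SD/median/quartiles of discrepant-test measurements plus the
    fraction falling in an inclusive window.

    Quartiles use linear interpolation of order statistics; percentages are
    reported to one decimal.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InsufficientDataError(f"{category or 'discrepancies'}: no values")
    low, high = window
    if low > high:
        raise ValidationError(f"window low {low} exceeds high {high}")
    n_in = int(np.count_nonzero((arr >= low) & (arr <= high)))
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return DiscrepancySummary(
        category=category,
        values=tuple(arr.tolist()),
        window=(low, high),
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        n_in_window=n_in,
        pct_in_window=round(100.0 * n_in / arr.size, 1),
    )


def flag_rate(n_flagged: int, n_total: int) -> float:
    """Percent flagged, 100 x n_flagged / n_total, to one decimal."""
    if n_total < 1:
        raise InsufficientDataError("n_total must be >= 1")
    if not (0 <= n_flagged <= n_total):
        raise ValidationError(f"n_flagged {n_flagged} outside [0, {n_total}]")
    return round(100.0 * n_flagged / n_total, 1)


def binarize_algorithm(result: InterpretationResult, category: str) -> Optional[bool]:
    """Algorithm label for one category as True/False, or None if not assessable."""
    if category == "obstruction":
        m = {Obstruction.OBSTRUCTED: True, Obstruction.NOT_OBSTRUCTED: False}
        return m.get(result.obstruction)
    if category == "restriction":
        m = {Restriction.RESTRICTED: True, Restriction.NOT_RESTRICTED: False}
        return m.get(result.restriction)
    if category == "dlco_abnormal":
        m = {Dlco.REDUCED: True, Dlco.ELEVATED: True, Dlco.NORMAL: False}
        return m.get(result.dlco)
    if category == "small_airway":
        m = {SmallAirway.FLAGGED: True, SmallAirway.NOT_FLAGGED: False}
        return m.get(result.small_airway)
    raise ValidationError(f"unknown category {category!r}")


def binarize_clinician(labels: ClinicianLabels, category: str) -> Optional[bool]:
    """Clinician label for one category as True/False, or None if unstated."""
    if category not in CATEGORIES:
        raise ValidationError(f"unknown category {category!r}")
    p: Presence = getattr(labels, category)
    return {Presence.YES: True, Presence.NO: False}.get(p)


def compare_cohort(
    results: Sequence[InterpretationResult],
    labels: Sequence[ClinicianLabels],
    categories: Sequence[str] = CATEGORIES,
) -> dict[str, ConcordanceTable]:
    """Per-category tables for matched (by record_id) results and labels.

    Records present on only one side are ignored; within a category a pair is
    excluded if either side is not assessable/unstated. Categories with zero
    usable pairs are omitted from the output.
    """
    by_id = {lab.record_id: lab for lab in labels}
    tables: dict[str, ConcordanceTable] = {}
    for cat in categories:
        pairs = [
            (binarize_algorithm(res, cat), binarize_clinician(by_id[res.record_id], cat))
            for res in results
            if res.record_id in by_id
        ]
        try:
            tables[cat] = build_table(pairs, category=cat)
        except InsufficientDataError:
            continue
    return tables
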