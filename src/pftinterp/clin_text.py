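"""Keyword extraction of clinician interpretation labels from free-text impressions.

Clinician impressions in PFT reports are short, macro-generated sentences
("Moderate obstruction.", "No evidence of restriction."). Extraction is
deliberately rule-based: a configurable per-category keyword lexicon matched
case-insensitively on word boundaries, with a token-window negation rule whose
scope is broken by sentence boundaries (period, semicolon, newline). A
category is *yes* if any keyword matches outside a negation scope, *no* if
every match is negated, *unstated* if nothing matches.

The default lexicon is a reconstruction and is expected to be edited per
institution; it can be loaded from / dumped to YAML.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .errors import ValidationError

__all__ = [
    "Presence",
    "Lexicon",
    "ClinicianLabels",
    "CATEGORIES",
    "extract_labels",
    "detect_negation",
    "tokenize",
]

#: the four label categories, in canonical order
CATEGORIES = ("obstruction", "restriction", "dlco_abnormal", "small_airway")

#: tokens that break negation scope
_BOUNDARY_TOKENS = frozenset({".", ";", "\n"})

_TOKEN_RE = re.compile(r"\w+|[.;\n]")


class Presence(str, enum.Enum):
    YES = "yes"
    NO = "no"
    UNSTATED = "unstated"


_DEFAULT_KEYWORDS = {
    "obstruction": [
        "obstruction",
        "obstructive defect",
        "obstructive ventilatory defect",
        "airflow limitation",
        "airflow obstruction",
    ],
    "restriction": [
        "restriction",
        "restrictive defect",
        "restrictive ventilatory defect",
        "reduced lung volumes",
    ],
    "dlco_abnormal": [
        "abnormal dlco",
        "dlco is abnormal",
        "reduced dlco",
        "dlco is reduced",
        "low dlco",
        "elevated dlco",
        "dlco is elevated",
        "reduced diffusion capacity",
        "impaired diffusion",
        "abnormal diffusion capacity",
    ],
    "small_airway": [
        "small airway dysfunction",
        "small airways dysfunction",
        "small airway disease",
        "late expiratory flattening",
    ],
}

_DEFAULT_NEGATION_CUES = ["no", "not", "without", "no evidence of", "absence of", "negative for"]


def tokenize(text: str) -> list[str]:
    """Lower-cased word tokens plus sentence-boundary tokens (``.``, ``;``, newline)."""
    return [t.lower() for t in _TOKEN_RE.findall(text)]


@dataclass(frozen=True)
class Lexicon:
    """Per-category keyword lists plus negation cues and window.

    ``negation_window`` is the maximum number of tokens between the end of a
    negation cue and the start of the keyword match for the match to count as
    negated. Matching is case-insensitive on word boundaries.
    """

    keywords: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_KEYWORDS.items()}
    )
    negation_cues: list[str] = field(default_factory=lambda: list(_DEFAULT_NEGATION_CUES))
    negation_window: int = 5

    def __post_init__(self) -> None:
        if self.negation_window < 1:
            raise ValidationError("negation_window must be >= 1")
        for cat in CATEGORIES:
            if not self.keywords.get(cat):
                raise ValidationError(f"lexicon category {cat!r} needs at least one keyword")

    @classmethod
    def from_yaml(cls, path) -> "Lexicon":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            keywords={k: list(v) for k, v in data.get("keywords", _DEFAULT_KEYWORDS).items()},
            negation_cues=list(data.get("negation_cues", _DEFAULT_NEGATION_CUES)),
            negation_window=int(data.get("negation_window", 5)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "keywords": self.keywords,
                    "negation_cues": self.negation_cues,
                    "negation_window": self.negation_window,
                },
                fh,
                sort_keys=False,
            )


@dataclass(frozen=True)
class ClinicianLabels:
    """Extracted clinician stance per category for one record."""

    record_id: str
    obstruction: Presence = Presence.UNSTATED
    restriction: Presence = Presence.UNSTATED
    dlco_abnormal: Presence = Presence.UNSTATED
    small_airway: Presence = Presence.UNSTATED

    @property
    def missing_interpretation(self) -> bool:
        """True iff no category was stated at all (including empty text)."""
        return all(getattr(self, c) is Presence.UNSTATED for c in CATEGORIES)


def detect_negation(tokens: Sequence[str], match_index: int, lex: Lexicon) -> bool:
    """True iff a negation cue ends within ``negation_window`` tokens before the match.

    ``tokens`` may contain sentence-boundary tokens; scope never crosses one.
    """
    if not (0 <= match_index <= len(tokens)):
        raise ValidationError(f"match_index {match_index} outside token sequence")
    start = max(0, match_index - lex.negation_window)
    cue_token_lists = [tokenize(c) for c in lex.negation_cues]
    for end in range(match_index, start, -1):
        # scope break between candidate cue end and the match
        if any(t in _BOUNDARY_TOKENS for t in tokens[end:match_index]):
            return False
        for cue in cue_token_lists:
            s = end - len(cue)
            if s >= 0 and [t.lower() for t in tokens[s:end]] == cue:
                return True
    return False


def _find_matches(tokens: list[str], phrase: str) -> list[int]:
    ptoks = tokenize(phrase)
    n = len(ptoks)
    return [
        i
        for i in range(len(tokens) - n + 1)
        if tokens[i : i + n] == ptoks
    ]


def extract_labels(
    record_id: str, text: Optional[str], lex: Optional[Lexicon] = None
) -> ClinicianLabels:
    """Extract the four category labels from one impression text.

    Empty or missing text yields all-unstated labels (and therefore
    ``missing_interpretation`` true).
    """
    lex = lex or Lexicon()
    if not text or not text.strip():
        return ClinicianLabels(record_id=record_id)
    tokens = tokenize(text)
    out: dict[str, Presence] = {}
    for cat in CATEGORIES:
        affirmed = negated = False
        for phrase in lex.keywords[cat]:
            for idx in _find_matches(tokens, phrase):
                if detect_negation(tokens, idx, lex):
                    negated = True
                else:
                    affirmed = True
        if affirmed:
            out[cat] = Presence.YES
        elif negated:
            out[cat] = Presence.NO
        else:
            out[cat] = Presence.UNSTATED
    return ClinicianLabels(record_id=record_id, **out)
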