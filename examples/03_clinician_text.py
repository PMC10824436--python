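"""Extract clinician interpretation labels from free-text impressions.

Matching is case-insensitive on word boundaries with a configurable keyword
lexicon; a negation cue within five tokens (same sentence) turns a match into
an explicit "no". A text stating none of the four categories is counted as a
missing interpretation.
"""

from pftinterp import extract_labels
from pftinterp.clin_text import CATEGORIES

impressions = {
    "t1": "Moderate obstruction. DLCO is reduced.",
    "t2": "No evidence of obstruction or restriction. Abnormal DLCO.",
    "t3": "Late expiratory flattening suggests small airway dysfunction.",
    "t4": "Technically limited study.",
    "t5": "",
}

print(f"{'id':4s} {'obstruction':12s} {'restriction':12s} {'dlco_abn':10s} "
      f"{'small_airway':13s} missing")
for rid, text in impressions.items():
    labels = extract_labels(rid, text)
    cells = [getattr(labels, c).value for c in CATEGORIES]
    print(f"{rid:4s} {cells[0]:12s} {cells[1]:12s} {cells[2]:10s} {cells[3]:13s} "
          f"{labels.missing_interpretation}")
# "unstated" is preserved as its own state: downstream concordance excludes
# such pairs instead of guessing, and t4/t5 count as missing interpretations.
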