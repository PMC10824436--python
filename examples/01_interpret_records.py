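"""Classify a handful of PFT records with the default rule thresholds.

Obstruction: FEV1/FVC < 0.70; restriction: TLC < 80 %pred; abnormal DLCO:
< 80 or > 120 %pred. Missing measurements come out "not_assessable", never
silently normal.
"""

from pftinterp import DLCO_WIDE, PFTRecord, interpret_record

records = [
    PFTRecord("copd-like", fev1_fvc_ratio=0.58, tlc_pct_pred=104, dlco_pct_pred=52),
    PFTRecord("fibrosis-like", fev1_fvc_ratio=0.84, tlc_pct_pred=62, dlco_pct_pred=48),
    PFTRecord("borderline", fev1_fvc_ratio=0.70, tlc_pct_pred=80.0, dlco_pct_pred=120.0),
    PFTRecord("incomplete", fev1_fvc_ratio=0.75),
]

print(f"{'record':14s} {'obstruction':16s} {'restriction':16s} dlco")
for rec in records:
    res = interpret_record(rec)
    print(f"{rec.record_id:14s} {res.obstruction.value:16s} {res.restriction.value:16s} "
          f"{res.dlco.value}")

# the same DLCO of 75 %pred is reduced by default but normal under the wider
# 70-130 %pred range some interpreters use
rec = PFTRecord("dlco-75", dlco_pct_pred=75)
print("\nDLCO 75 %pred, default 80-120 range:", interpret_record(rec).dlco.value)
print("DLCO 75 %pred, wide 70-130 range:   ", interpret_record(rec, DLCO_WIDE).dlco.value)

# Equality with a cutoff is read as normal ("borderline" above), and the
# missing TLC/DLCO of "incomplete" are not assessable rather than normal.
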