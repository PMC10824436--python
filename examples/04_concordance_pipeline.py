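"""End-to-end agreement study on a synthetic cohort with imperfect clinicians.

Simulates 400 tests with known truth (30 % obstruction, 25 % restriction,
30 % abnormal DLCO, 25 % forced small-airway prevalence among non-obstructed),
clinician impressions carrying a 5 % label-flip rate and 3 % missing reports,
then runs the full pipeline: rule interpretation + SADI flag vs text-extracted
clinician labels, per-category 2x2 tables with agreement rate and Cohen's
kappa, and the discrepancy distribution for obstruction.
"""

from pftinterp import (
    CohortNorm,
    CohortParams,
    compare_cohort,
    compute_sadi,
    extract_labels,
    flag_small_airway,
    generate_cohort,
    interpret_record,
    summarize_discrepancies,
)
from pftinterp.concordance import binarize_algorithm, binarize_clinician

params = CohortParams(
    n=400, obstruction_prev=0.30, restriction_prev=0.25, dlco_abnormal_prev=0.30,
    small_airway_prev=0.25, clinician_error_rate=0.05, clinician_missing_rate=0.03,
    seed=20180301,
)
cohort = generate_cohort(params)
norm = CohortNorm.from_moments(params.sadi_mean, params.sadi_sd)

results = []
for rec in cohort.records:
    res = interpret_record(rec)
    sres = compute_sadi(cohort.curves[rec.record_id])
    results.append(res.with_small_airway(flag_small_airway(res, sres, norm)))
labels = [extract_labels(r.record_id, r.clinician_text) for r in cohort.records]

tables = compare_cohort(results, labels)
print(f"{'category':14s} {'n':>4s} {'agree%':>7s} {'kappa':>7s} {'excluded':>9s}")
for cat, t in tables.items():
    print(f"{cat:14s} {t.n:4d} {t.agreement_pct:7.1f} {t.kappa:7.3f} {t.excluded:9d}")

# ratios of the tests where the two raters disagreed on obstruction
by_id = {r.record_id: r for r in cohort.records}
lab_by_id = {l.record_id: l for l in labels}
disc = [
    by_id[r.record_id].fev1_fvc_ratio
    for r in results
    if (a := binarize_algorithm(r, "obstruction")) is not None
    and (c := binarize_clinician(lab_by_id[r.record_id], "obstruction")) is not None
    and a != c
]
if disc:
    s = summarize_discrepancies(disc, (0.65, 0.75), "obstruction")
    print(f"\nobstruction discrepancies: n={s.n}, mean ratio {s.mean:.2f}, "
          f"{s.pct_in_window:.1f}% inside [0.65, 0.75]")
# With a 5 % flip rate agreement sits in the mid-90s and kappa around 0.9;
# excluded counts show missing impressions and (for small airway) the
# obstructed tests where the flag does not apply.
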