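# Methods

## Rule classification

Each interpretation axis is a one-dimensional threshold rule applied to a
stored-precision measurement; no re-rounding happens before comparison.
Cutoffs are strict as written — FEV1/FVC < 0.70, TLC < 80 %pred,
DLCO < 80 or > 120 %pred — so a value exactly on a cutoff is normal. The
choice matters in practice: interpretation disagreements cluster in the gray
zone around the cutoffs, and a tie-break convention must be fixed and tested.
Missing inputs map to `not_assessable` rather than to the normal category,
because tests without an interpretation are analytically interesting in
their own right (they are tallied as exclusions downstream, not absorbed
into agreement counts). `RuleConfig` carries the four thresholds; each
result embeds the exact config snapshot that produced it. The `dlco_wide`
preset (70–130 %pred) reflects the wider gas-transfer normal range some
interpreters use and exists to support sensitivity analyses.

## SADI: segment-regression angle of the expiratory limb

The curve is the expiratory limb only, parameterized by volume expired since
the start of expiration (liters, strictly increasing from 0) against flow
(L/s). Landmarks:

- **A** — the first sample attaining maximum flow (peak expiratory flow).
  Ties resolve to the earliest sample.
- **C** — the first zero-flow crossing after A, linearly interpolated
  between the bracketing samples; if flow never reaches zero the limb is
  closed at the last sample. The expiratory vital capacity is the volume at
  C, measured on the curve itself so the index is self-contained and does
  not depend on the numeric FVC field.
- **B** — flow linearly interpolated at 0.75 × VC. If B does not fall
  strictly after A (peak beyond 75 % of VC) the curve is degenerate and an
  error is raised rather than a meaningless angle returned.

Ordinary least squares over *all* samples in each segment — not a two-point
chord — gives the two slopes; the interpolated B point joins both segments
and the interpolated C point joins B→C, which stabilizes short tails. Each
segment must carry at least 3 points (configurable). The angle is

    angle = 180° − |atan(s_AB) − atan(s_BC)|,

which is the interior angle at B between the fitted directions; it lives in
(0°, 180°] and equals 180° exactly when the segments are collinear.

**Aspect ratio.** The two axes carry different units, so the visual angle
depends on the plot aspect. Slopes are divided by an `aspect` parameter
(L/s per liter) before the arctangents; the default 1.0 means "1 L on the
volume axis spans the same distance as 1 L/s on the flow axis". The angle is
invariant under uniform rescaling of both axes and under volume translation
(regression slopes are translation-invariant), but changes with `aspect`;
results record the aspect used. Raw samples are fitted as digitized — no
smoothing or resampling is applied.

## Lower limit of normal

For the angles of a cohort's non-obstructed tests, LLN = mean − 1.64 × SD,
the one-sided 5th percentile under normality. SD is the sample standard
deviation (ddof = 1); with cohort sizes in the thousands the distinction
from the population SD is far below reporting precision. Published cohort
moments can be supplied directly via `CohortNorm.from_moments`. Norm
summaries report to one decimal; flagging compares at full stored precision
with a strict `<`. The flag is only defined for non-obstructed tests —
obstructed tests and tests without a usable curve come out
`not_assessable`.

## Clinician-text extraction

Extraction is rule-based by design: impressions in PFT reports are short
macro-generated sentences, and a transparent keyword lexicon is auditable
and institution-editable in a way a learned model is not. Tokenization is a
`\w+` word tokenizer that also emits sentence-boundary tokens (period,
semicolon, newline); keyword phrases match as contiguous token sequences,
case-insensitively, which gives word-boundary semantics (no match inside
other words). A match is negated when a negation cue ("no", "without", "no
evidence of", …) ends within `negation_window` tokens (default 5) before it
with no sentence boundary in between. Per category: any non-negated match ⇒
`yes`; matches but all negated ⇒ `no`; no match ⇒ `unstated`. A text
stating nothing in any category — including empty text — is a missing
interpretation. The default lexicon is a reconstruction of typical reporting
language and ships as editable data (`Lexicon.from_yaml`/`to_yaml`); adding
keywords can move a category from `unstated` to `yes`/`no` but never the
reverse, a property the tests enforce.

## Concordance

Per-category binarization: obstructed vs not; restricted vs not; abnormal
DLCO (reduced *or* elevated) vs normal, matching the single abnormal-DLCO
reporting axis; flagged vs not for small airway. Pairs with
`not_assessable`/`unstated` on either side are excluded from the 2×2 and
counted separately, and every rate is reported with its own denominator —
per-category denominators differ (not every test has TLC or DLCO measured,
and the small-airway comparison is restricted to non-obstructed tests), so
a rate without its n is not interpretable. Agreement rate is
100·(a+d)/n to one decimal; Cohen's kappa is (p_o − p_e)/(1 − p_e), exact
1.0 under perfect agreement with both classes present, and deliberately
*undefined* (an error/None, not a number) when the marginals are degenerate.
Kappa is reported to three decimals. Discrepancy summaries use inclusive
window bounds and linear-interpolation quartiles (a stated convention, since
several are in use).

## Synthetic data

The curve family is `flow = pef·v/v_peak` on the rising leg and
`pef·((vc − v)/(vc − v_peak))^γ` on the descent, sampled on a uniform volume
grid with the exact peak point inserted so that γ = 1 is exactly
piecewise-linear (and therefore reads exactly 180°, a calibration anchor the
tests assert to 1e-6). γ is the single concavity knob emulating
late-expiratory flattening. This is a geometric stand-in, not a physiology
model: it has no effort dependence, no wave-speed limitation, no
intra-breath variability, and its noise (optional Gaussian flow jitter) is
white rather than autocorrelated. Passing tests therefore demonstrate the
correctness of the geometry, rules and statistics — not performance on real
digitized loops.

Defaults are chosen to be clinically plausible: vc 4 L, pef 8 L/s, peak at
10 % of VC, 50 samples per curve; cohort angle law mean 156.5°, SD 16.9°
(the reference non-obstructed population). Cohort values are drawn strictly
separated from the rule cutoffs (obstructed ratios in 0.45–0.66, normal in
0.72–0.88, and similarly for TLC/DLCO) so truth recovery by the interpreter
is exact by construction, which is what an end-to-end zero-error test needs.

**γ ↔ angle mapping.** The map from γ to the noise-free angle is tabulated
empirically on a seeded grid and inverted by interpolation; it is strictly
decreasing on γ ∈ [1, 4] for the reference shape and turns around beyond
that (once the tail is flat enough it also drags the A→B fit down), so
inversion is restricted to [1, 4], i.e. angles ≈ 112°–180°. Cohort curves
share a fixed pef/vc shape ratio (pef = 2·vc) so the tabulated map stays
exact under the per-subject scale (the angle is similarity-invariant).

**Truncation at 180°.** Any two fitted lines subtend at most 180°, so the
index is geometrically capped; target angles drawn from N(mean, SD) are
clipped to the achievable range. At the default law about 8 % of the mass
lies above 180°, which shifts the realized cohort mean down by ~0.6° and
shrinks the SD slightly; the LLN recovered from a 4,711-subject cohort lands
within ~1.1° of the moment-derived value, inside the tolerance the tests
use. Small-airway truth is taken from the *computed* angle of the generated
curve against the nominal LLN (with a 1° guard band when a prevalence is
forced), so boundary misclassification cannot occur by construction.

One global seed fans out to per-subject `SeedSequence` substreams keyed by
subject index, so a cohort's first k subjects are identical regardless of n.

## PDF report adapter

Vendor report dialects differ and none is canonical, so the adapter is a
contract plus configuration: a label→field mapping for the numeric table, an
impression heading, and a two-reference-tick affine calibration per axis for
converting the flow–volume panel's vector segments to physical points
(sorted by volume and re-zeroed at the first sample). The pure mapping and
calibration logic is implemented and tested on pre-extracted inputs; actual
PDF I/O is delegated to the optional `pdfplumber` dependency, imported
lazily. Image-only scans (no text layer) are rejected explicitly; an
unresolvable panel calibration degrades to "record without curve" with a
warning rather than failing the extraction.

## Problem sizes and numerical choices

The test suite and acceptance script use cohorts of 40–4,711 subjects and
50-sample curves, sizes at which every statistic in play is stable (the
standard error of the 4,711-draw LLN is ≈ 0.38°, well inside the ±1°
assertion). Collinearity assertions use 1e-6–1e-9 tolerances; agreement
rates and percentages round to one decimal, kappa to three, matching
conventional reporting. File writers emit floats via `repr` (shortest
round-trip form) and fixed row order, so write→read is the identity and
reruns are byte-identical.

## Known limitations

- No severity grading, z-score/LLN-based spirometry rules, bronchodilator
  response, air trapping, or early-restriction (normal TLC + low VC)
  pattern; no hemoglobin adjustment of DLCO.
- SADI is computed on raw digitized samples; heavily noisy or sparsely
  digitized limbs may need more samples rather than smoothing.
- The lexicon defaults cover common phrasing only; institution-specific
  macros should be added to the YAML lexicon.
- The synthetic curve family cannot represent every real limb shape
  (e.g. knee-shaped rise, coughs, terminal flow oscillations).
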