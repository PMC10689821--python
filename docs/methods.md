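# Methods

This note documents the model, the numerical conventions, the synthetic
cohort that stands in for the restricted clinical data, and the design
choices made where the published description of the system left the
design open.

## Problem and data model

The system predicts overt thyrotoxicosis — serum free T4 strictly above
the upper reference limit (default 1.78 ng/dL) — at a *target* date from
wearable sleep heart-rate data, anchored by one earlier blood test of the
same patient (the *referred* TFT).

Thyroid state labeling uses closed reference intervals
(free T4 ∈ [0.89, 1.78] ng/dL, TSH ∈ [0.3, 4.0] mIU/L): values exactly on
a boundary are *inside* the range, and the overt states require a strict
inequality. Only the free-T4 upper bound is stated strictly in the
source material; treating the intervals as closed everywhere is this
package's convention (a TSH of exactly 0.3 with normal free T4 is
euthyroid, not subclinical thyrotoxicosis). Ranges are configurable
because reference intervals are assay-specific.

### Sleep windows

A sleep session belongs to the calendar date its sleep **ends**; sessions
ending on the same date are concatenated chronologically (the published
rule assigns sessions to dates but states no selection rule, so nothing
is discarded). HR samples outside (20, 250) bpm are dropped with a
logged count.

The N-day window for a TFT at date *t* covers nights dated
[*t* − N, *t* − 1] (default N = 10), following the literal "days prior
to the test date". Since a sleep ending on the morning of *t* still
precedes a daytime blood draw, `include_anchor_morning=True` shifts the
span to [*t* − N + 1, *t*]. Missing nights are absent, never imputed.

A pair is usable when its window has ≥ 3 nights and ≥ 300 pooled samples
(configurable). No minimum is published; moment and divergence
estimates from fewer samples are unstable, and the cutoffs are roughly
one-third of a typical window's content at consumer-device cadence.
The window-length sweep relaxes the rule to `min(3, N)` nights (with a
proportional sample floor) so that N < 3 remains evaluable.

## Features

Moments are the biased (population) estimators: RSD = population SD /
mean, skewness the third standardized moment, kurtosis the *excess*
fourth standardized moment. Whether the published RSD is a ratio or a
percentage, and whether kurtosis is raw or excess, is unstated; ratio and
excess were chosen. A zero-variance window defines skewness = kurtosis
= 0 so constant-HR inputs stay usable.

Histograms use 1-bpm integer-aligned bins (device resolution; no
published discretization). In `featurize` the shared range spans the
union of both windows with the top edge extended one bpm past the
maximum, so an integer-valued maximum occupies its own bin rather than
numpy's closed final bin — this also makes the union-range histogram
exactly equivalent to a fixed global 20–250 bpm grid, which the dataset
builder uses as a per-pair cache (bins empty in both histograms
contribute nothing to the divergence; the equivalence is asserted in the
test suite).

Jensen–Shannon divergence is computed in nats (bounded by ln 2 ≈ 0.6931)
with the 0·log 0 = 0 convention; base 2 is available by flag. The
quotient feature divides Δmean HR by max(TSH_ref, 0.025 mIU/L) — the
floor is the assay reporting floor and prevents blow-up in fully
suppressed TSH.

## Cases and augmentation

All ordered within-patient combinations of usable pairs are cases (a
patient with k pairs yields k(k−1)); the label derives only from the
target pair's free T4. Interpolated pairs are placed every `step_days`
(default 7) strictly between adjacent TFTs, linear in the raw
concentrations (log-linear TSH available, since TSH spans orders of
magnitude); each carries the *actual* HR window of its date and is
flagged `interpolated`. Interpolated pairs join training as referred
and as target but are never evaluation targets. The published pair
growth (662 → 2,711 over ≥ 4-week gaps) is consistent with roughly
weekly granularity, which motivated the default step.

## Classifier

Per-feature empirical quantile transform to uniform [0, 1]
(`QuantileTransformer`, fitted on training cases only and refitted in
every cross-validation fold — leakage-safe; whether the original system
refitted per fold is unstated), then a LightGBM binary classifier. No
hyperparameters are published; the defaults here are 200 trees, learning
rate 0.05, 31 leaves, minimum 20 cases per leaf, and no row/column
subsampling, chosen to keep fits deterministic (single-thread,
`deterministic=True`) and weight-invariant. Exact invariance to uniform
duplication of the training set additionally requires the backend's
histogram binning not to depend on row counts (`max_bin` above the
number of distinct values and `min_data_in_bin=1`, exposed in
`ModelConfig`); with the library defaults (255 bins, ≥ 3 rows per bin)
the invariance is approximate only.

Feature importance reports gain (normalized to sum to 1) and split
counts, ranked 1..8 per model with ordinal tie-breaks. The "gain and
split" combined criterion is implemented as the per-model mean of the
two ranks, averaged across models — the combination rule is not
published and this is the simplest symmetric choice.

## Evaluation

Modified LOOCV: for each observed target pair P, training uses every
case of every patient **except** any case involving P; one model is
fitted per target fold (all test cases of a fold share the exclusion
set, so per-case refits would be identical — this is an exact
optimization, not an approximation). Per-referred probabilities are
averaged arithmetically and thresholded at 0.5 (no published threshold;
configurable). The published worked example's training list contains an
apparent typo ("Tb2 → Ta3"); cross-patient cases contradict the
system's within-patient definition and are never generated.

Metrics are reported to two decimals; exact ratios are kept internally
and zero-denominator ratios are NaN, never 0. Excluding subclinical
thyrotoxicosis removes only label-negative targets, so TP and FN are
invariant under the toggle (asserted in tests). Note the published
subclinical-excluded table's counts sum to 391 while its legend says 399
data; the counts are treated as canonical here.

Group comparisons follow the published analysis style: Student t
(mean ± SD) for normal-shaped variables, Mann-Whitney (median, IQR)
otherwise, chi-square for proportions.

## Synthetic cohort

Real cohort data are IRB-restricted, so the generator emulates the
statistical structure the pipeline assumes:

- **Groups.** 70% thyrotoxic, 19% euthyroid, 11% hypothyroid patients;
  3 or 4 TFTs (38/137 split at 175 patients) at 28–42-day intervals.
- **Free T4 dynamics.** Treatment starts at the first visit; latent
  free T4 relaxes exponentially toward a patient-specific euthyroid
  setpoint, rate ~ U(0.03, 0.075)/day (hypothyroid titration scaled by
  0.4 — levothyroxine up-titration is slower than antithyroid response).
  Initial free T4 ~ N(2.6, 1.1) truncated to [1.45, 6.5] ng/dL
  (thyrotoxic) or N(0.55, 0.12) on [0.2, 0.8] (hypothyroid).
- **TSH.** log₁₀ TSH responds linearly to free T4 measured 55 days
  earlier (pituitary lag — the mechanism that produces the large
  subclinical-thyrotoxicosis stratum), slope 3.5 decades per ng/dL above
  the setpoint and 1.6 below, saturating at 0.025 and 100 mIU/L.
  Emitted TFTs add assay noise (0.05 ng/dL; 5% relative TSH).
- **HR coupling.** Night mean = patient baseline (N(62, 5) bpm) +
  22 bpm × (same-day latent free T4 − 1.335), i.e. ~11 bpm per
  0.5 ng/dL, the association size reported for wearable resting HR in
  thyrotoxicosis; night-to-night jitter 3 bpm, within-night sample SD
  5 bpm, 250–450 integer samples per night, 10% of nights missing.

These defaults put the visit-state mix near the published cohort
composition (measured ≈ 17/39/35/5/4% overt-toxic/subclinical-toxic/
euthyroid/sub-hypo/overt-hypo at n = 300 versus the published
15/40/35/5/5). Truth tables record the latent values and states for
parameter-recovery tests.

**What the generator does not emulate:** circadian within-night HR
structure, activity/stress/alcohol confounders, device artifacts beyond
range clipping, relapse dynamics, and between-patient heterogeneity in
the HR–fT4 slope. Under strong coupling the synthetic task is therefore
*easier* than the clinical one — end-to-end runs reach sensitivity and
specificity above 90%, where the published system reports ~86% — so
passing recovery tests demonstrates correctness of the machinery, not
clinical performance. The null configuration (coupling slope 0) checks
the other direction: with no HR signal the pipeline's Youden index sits
near zero.

## Problem sizes and runtime choices

End-to-end checks use 40-patient cohorts (≈ 150 observed pairs,
≈ 10,000 augmented cases, one model fit per fold) with five fixed seeds
for the recovery experiment and three for the null; the window sweep
uses 10 patients, 60 trees, N = 1..15 in both modes; combinatorics
checks use 175 patients with shortened nights (counting does not depend
on night content). These sizes make the full suite run in minutes while
keeping every structural property at full fidelity.

## Known limitations

- The headline clinical metrics (86.14% sensitivity etc.) are properties
  of the restricted real cohort and are reproduced here only as the
  arithmetic of the published confusion counts, not re-derived from data.
- The published case total (2,182 from 662 pairs) is not attainable from
  any pure 3-or-4-TFT mix at 175 patients; the combinatorics check uses
  a mix over {3, 4, 5, 7} TFTs that matches both published totals
  exactly.
- The derived-feature *search* ("product/quotient of two features") is
  not reproducible from its description; only the selected quotient
  feature is implemented.
- Interpolated pairs adjacent to a held-out target still encode a linear
  mixture of its blood values; the exclusion rule removes only cases
  that reference the pair itself, mirroring the published scheme.
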