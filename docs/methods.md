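# Methods

## Setting and model

The package evaluates triage rules for suspected nonvariceal upper-GI
bleeding (NVUGIB) in the emergency department. The outcome is the presence of
a high-risk endoscopic lesion (HREL) at subsequent endoscopy; HREL status is
an input label here, never inferred from images. Two predictors are compared
on the same patients:

* the Glasgow-Blatchford score (GBS), an integer 0–23; and
* a combined score `S = min(GBS + 23·[bloody NGA], 23)`, where NGA is the
  nasogastric aspirate, dichotomised bloody vs non-bloody (coffee-ground,
  bile-like and clear aspirates all count as non-bloody).

The clinical rule corresponding to S is two-way: low-risk iff non-bloody NGA
and GBS ≤ t. For any t < 23 this is identical to `S ≤ t` (property-tested
exhaustively); t = 23 is rejected because it would label bloody patients
low-risk, defeating the saturation the cap encodes.

## GBS scoring

Component points follow the original integer-banded criteria: BUN (mmol/L,
urea nitrogen) 6.5–7.9→2, 8.0–9.9→3, 10.0–24.9→4, ≥25→6; hemoglobin (g/L)
for men 120–129→1, 100–119→3, <100→6 and for women 100–119→1, <100→6;
systolic BP (mmHg) 100–109→1, 90–99→2, <90→3; pulse ≥100→1; melena→1;
syncope→2; hepatic disease→2; cardiac failure→2. Bands are closed on their
printed endpoints (6.5 ≤ BUN < 8.0 scores 2). BUN reported in mg/dL is
converted with the urea-nitrogen molar factor 2.8 mg/dL per mmol/L.
Hemoglobin is held internally in g/L; cohort CSVs carry g/dL, the common
clinical unit. Scoring is validated against an independently written
interval-table oracle on a grid covering every band and endpoint, and a
monotonicity property (worsening any single input never lowers the total).

## Cohort reconstruction

The study cohort (n = 115, 35 with HRELs) is not deposited, but its
patient-level joint distribution of (GBS, bloody NGA, HREL) is fully
identified by printed summaries: cumulative rule-out counts at cutoffs 0..17
for both scores by HREL stratum, plus the bloody split per stratum (24/11).
Because a non-bloody patient's combined score equals their GBS while every
bloody patient's combined score is 23, first differences of the two
cumulative tables give, per score value and stratum, the non-bloody counts
(combined-score table) and total counts (GBS table); their difference is the
bloody patients' GBS distribution. Any negative difference is rejected as an
inconsistent-tables error. Both cumulative tables reach their stratum totals
at cutoff 17, so all GBS values are ≤ 17 and the combined table needs no
rows between 18 and 22. Records are materialised with ids P001–P115 in the
stable order (HREL desc, bloody desc, GBS asc), making the reconstruction
deterministic and byte-reproducible; re-aggregating the records reproduces
both input tables exactly (round-trip test). Non-bloody aspirate categories
(coffee-ground / bile-like / clear) are assigned to match the printed
per-stratum category counts; their joint with GBS is not identifiable and is
fixed by the deterministic assignment order — no analysis depends on it.
Clinical variables not identifiable from the tables (age, blood pressure,
medications) are left absent in the reconstructed records, not imputed.

## Diagnostic evaluation

Threshold sweeps count, at each cutoff k, patients with score ≤ k by stratum;
sensitivity = 100·(n_with − cum_with)/n_with and specificity =
100·cum_without/n_without, with cumulative percentages out of the whole
cohort. The operating threshold for each score is the **largest** cutoff
whose sensitivity stays ≥ 98%, a rule-out floor chosen so that raising the
cutoff never misses patients needing endoscopic treatment; the floor is a
parameter (`min_sensitivity`, default 98).

All proportion CIs are Clopper-Pearson exact intervals (beta quantiles),
which have the correct degenerate endpoints (lower = 0 at 0/n, upper = 100%
at n/n) and are equivariant under swapping successes and failures. Group
comparisons use the pooled-variance Student t-test for means, and for
proportions the chi-square test without continuity correction (default) or
Fisher's exact test; Fisher is property-tested against direct hypergeometric
enumeration.

Table percentages are rounded to one decimal with **ties to even** — the
convention of R, in which cumulative specificity ties such as 33/80 = 41.25%
arise and must round to 41.2 to match the source tables.

## ROC and the DeLong machinery

AUC is the tie-corrected Mann–Whitney estimator; with integer scores ties are
heavy, and the 0.5 tie weight is what makes the reconstructed-cohort GBS AUC
exactly 1790/2800 = 0.639. Placement values are computed from midranks in
O(N log N) and checked against the explicit pairwise double loop. The
variance of one AUC is S₁₀/n + S₀₁/m (sample variances of case and control
placements); CIs use the normal approximation truncated to [0, 1]. The paired
test for two scores on the same patients uses
var(ΔAUC) = (S₁₀ᵃ + S₁₀ᵇ − 2S₁₀ᵃᵇ)/n + (S₀₁ᵃ + S₀₁ᵇ − 2S₀₁ᵃᵇ)/m with z
referred to the standard normal; identical scores (zero variance of the
difference) return z = 0, p = 1 by convention. Scores are oriented
higher = more likely HREL; there is no automatic direction flipping. The
implementation is cross-checked against pROC's DeLong routine, a jackknife
variance (within 10%), and a stratified-bootstrap test on a small cohort.

## NRI and IDI

Continuous NRI: among events, P(risk up) − P(risk down); among non-events,
the signs reverse; ties contribute zero; total = sum of the two components
(range [−2, 2], each component in [−1, 1]). IDI is the change in
discrimination slope, (mean risk | event − mean risk | non-event), new minus
old; as a difference of two slopes each in [−1, 1] its range is [−2, 2] (it
lies in [−1, 1] whenever neither model discriminates worse than chance).
Because the source analysis does not state how integer scores were mapped to
risks, the default maps each score to predicted probabilities by a univariate
logistic fit on the analysis cohort (IRLS-verified against an independent
implementation); perfect separation is flagged and falls back to rescaled
midranks, preserving the score ordering. A `raw_scores` mode feeds the scores
themselves into the NRI/IDI formulas; on the reconstructed cohort the
score-based NRI enumerates by hand (only bloody patients move, all upward):
24/35 − 11/80 ≈ 0.548. No external numeric targets exist for the calibrated
NRI/IDI values, so they are covered by property tests (zero on identity,
antisymmetry under swapping models, bounds) rather than value matching.

## Synthetic cohorts

The generator emulates the study conditions hierarchically: HREL ~
Bernoulli(0.304); bloody NGA ~ Bernoulli(0.686 | HREL, 0.138 | no HREL); GBS
from a per-stratum distribution on 0..23 — by default normals with the
stratum means/SDs 11.3/3.7 and 9.4/4.2 discretized to integer cells and
truncated, or empirical per-score weights (optionally per (stratum, bloody)
cell, which reproduces the full joint and hence both AUCs). Raw clinical
variables are then inverse-generated to realise the drawn GBS exactly: one
decomposition of the target into component points is sampled uniformly from
the exhaustive enumeration (≤ 5·4·4·2⁴ per target), and each raw value is
drawn uniformly inside the band scoring those points. Open-ended bands use
bounded physiologic surrogates: BUN ≥ 25 mmol/L in [25, 60], BUN "normal" in
[2, 6.4], hemoglobin < 100 g/L in [40, 99] (high bands to 170/160), SBP < 90
in [60, 89] (normal to 180), pulse in [50, 99] / [100, 160]. Every total
0–23 is feasible for both sexes (enumeration-verified), and the round-trip
score(inverse(g)) = g is exact for every draw. Covariates not in the score
(age ~ N(74.8, 18.3) clipped to [18, 100], sex male with probability 0.635,
hematemesis 0.574, non-bloody aspirate categories at ratio 52:6:22) are
sampled independently, matching the study marginals purely for CSV realism —
the generator models no correlation between them and the score, so passing
recovery tests say nothing about covariate structure in real data. A single
`numpy` Generator seeded from the config drives all draws; identical configs
give byte-identical CSVs.

Recovery tests run at n = 100 000 — large enough that 3-standard-error boxes
on the conditional probabilities and stratum means are tight (≈ ±0.5%
absolute on probabilities) while the whole suite stays fast — and check the
full pipeline (re-scoring every synthetic patient from raw variables) lands
both AUCs within ±0.02 of the source-cohort values.

## Numerical and design choices

* Positive test = "predicted high-risk" (score > cutoff, or bloody NGA);
  condition = HREL present. The source's performance table prints its
  predictive-value columns in the opposite orientation (its "NPV" cells are
  the HREL rate among patients *kept* for endoscopy: 35/112 and 35/88, both
  exactly Clopper-Pearson); this package reports conventional PPV/NPV and
  asserts the identified printed fractions only as CP checks.
* Chi-square without Yates correction, d.f. = 1; the comparisons it backs are
  reported only against a p < 0.001 bound, which either convention satisfies.
* The bootstrap for NRI/IDI CIs is stratified on the outcome (both strata
  persist in every resample) and fully seeded.
* Analysis drivers use fixed seeds and modest sizes (50k for the synthetic
  validation driver) so their outputs are stable run to run.

## Known limitations

* The reconstruction recovers the exact joint of (GBS, bloody, HREL) but not
  of the unprinted covariates; summaries of those columns reflect assignment
  conventions, not data.
* The sensitivity-floor threshold rule inherits the fragility of small
  samples: with 35 events, one reclassified event moves sensitivity by 2.9
  percentage points, so the selected cutoffs are not stable under resampling.
* DeLong CIs use the normal approximation; near-degenerate AUCs (0 or 1)
  get truncated rather than exact intervals.
* The logistic calibration for NRI/IDI is fitted and evaluated on the same
  cohort (apparent, not cross-validated, reclassification).
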