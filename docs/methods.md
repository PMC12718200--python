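# Methods

## What the pipeline models

The package analyses the baseline of a cohort of women with obesity
(BMI ≥ 30 kg/m²) and early-stage endometrial cancer or atypical
hyperplasia. Exposures are three composite diet/lifestyle quality indices
derived from food-frequency intakes (g/d, kJ/d), activity (min/wk of
moderate-or-vigorous activity) and anthropometry; outcomes are glycemic
control, body composition, quality of life and anxiety/depression. The
analysis is cross-sectional: regression estimates are associations, not
effects.

## Index construction

**MDS.** Nine components scored 0/1 against medians computed *within the
analytic sample being scored*. Beneficial components (fruit+nuts,
vegetables, cereals, legumes, fish/seafood, MUFA:SFA ratio) score 1 at or
above the median — the at-median boundary counts as adherent; dairy and
combined red+processed meat score 1 below the median; alcohol scores 1 for
5 ≤ g ethanol/d < 25 (half-open window: 25 g/d scores 0). A zero-SFA
record with positive MUFA gets an infinite ratio (scores 1 whenever the
median is finite) and is logged. Because components are median-relative,
adding a constant to every participant's value for one component leaves all
scores unchanged; this is tested.

**Modified WCRF/AICR (0–6).** Six recommendations scored 1/0.5/0: body
fatness (BMI 18.5–24.9 full, 25–29.9 partial), activity (≥ 150 min/wk
full, 75–149 partial), energy-dense food & sugary drinks, plant foods,
red/processed meat (red < 510 g/wk gate; processed < 21 g/wk full,
< 100 g/wk partial), alcohol (abstention full, ≤ 14 g/d partial). For the
two-part components (energy density + sugary drinks; plant grams + fibre)
the riskier subcomponent governs, keeping every component in {0, 0.5, 1}.
The salt, supplement and breastfeeding recommendations are not scored.

**EHLI (0–9).** Smoking (never/former/current → 1/0.5/0), alcohol (0 g/d
full, ≤ 10 partial), activity and BMI (as above), fruit & vegetables
(≥ 400 g/d full, ≥ 200 partial), weight-gain-promoting drinks (none full,
≤ 250 g/d partial), red+processed meat (≤ 20 g/d full, ≤ 70 partial),
unprocessed grains + legumes (≥ 150 g/d full, ≥ 75 partial), dairy
(≤ 500 g/d full, ≤ 700 partial).

Legumes count inside the fruit-and-vegetable aggregate for WCRF and inside
the grains aggregate for EHLI. All WCRF/EHLI thresholds live in
`CutpointConfig` (JSON round-trippable); the defaults follow the
standardized WCRF/AICR scoring conventions and common healthy-lifestyle-index
practice, chosen once and documented here. The EHLI meat, grain and dairy
cut-points have no single canonical published value; the defaults are
field-realistic daily-gram conventions and are deliberately configuration,
not code. Activity is a single combined moderate-or-vigorous minutes
column; if a source instrument distinguishes vigorous minutes, apply any
moderate-equivalent weighting before the column enters the pipeline.

**Tertiles.** Cut at the empirical 1/3 and 2/3 quantiles (linear
interpolation); ties at a boundary all go to the lower tertile, so with
discrete totals the top group can be well under a third of the sample.
Tertile 3 flags "good" quality. All-identical totals collapse to one
tertile with a warning.

## Outcome scoring

HOMA-IR is glucose (mmol/L) × insulin (as recorded) / 22.5; a missing input
propagates, a nonpositive recorded input raises. FACIT subscales are
prorated by n_items/n_answered when more than half the domain's items are
answered; the overall score requires more than 80% of all 43 items *and*
all five subscales. HADS reuses the same proration thresholds; severity
bands are implemented as the partition [0,7], (7,10], (10,14], (14,21] so
fractional prorated scores always receive exactly one category. Prorated
scores are kept at full precision — rounding before modelling would discard
information. The set of reverse-scored FACIT items is instrument-version
dependent and therefore part of the scoring key (`FacitKey`), validated for
completeness; the default key is a synthetic stand-in with the correct
domain structure (7/7/6/7/16).

## Exclusion cascade

Order: implausible energy → missing demographics → missing activity; each
excluded record carries the first criterion it fails. Two bound modes:
`fixed` (2568–17 031 kJ/d, default — it makes tests exact and matches the
realized window of the ±3 SD rule) and `data_driven`
(exp(mean ± 3·sd of log energy), sample SD, computed on all questionnaire
completers before any other exclusion). The kJ→kcal constant is the
thermochemical 4.184, under which the fixed bounds are ≈ 614 and
≈ 4071 kcal. "Missing demographics" is operationalized as missingness in
any covariate of the most fully adjusted model (age, education, marital
status, smoking, comorbidity count); the list is configurable because the
criterion's exact field set is not canonical.

## Association models

Exposures are z-standardised with the sample-SD (n−1) convention within
each model's complete-case sample, so coefficients are per-SD effects.
Models are OLS with indicator-coded categorical covariates (reference
levels: education "high school or less", marital status "partner", smoking
"never", comorbidities "0"); design matrices are checked for rank before
fitting. Covariate sets: MDS adjusts for age, total energy, education,
marital status, smoking, comorbidities (0 vs 1+), activity and BMI; WCRF
drops BMI and activity; EHLI additionally drops smoking — each index omits
what it already contains. BMI as an outcome is structurally skipped for
WCRF and EHLI. HbA1c, fasting insulin, fasting glucose and HOMA-IR are
modelled as natural logs with exponentiated estimates and CIs (these
measures are strictly positive; a zero raises rather than being offset).
The fixed list of log-modelled outcomes is configuration; tertile-wise
descriptive comparisons use chi-square for categoricals and a Shapiro–Wilk
gate (α = 0.05 on group-centred values) to choose ANOVA vs Kruskal–Wallis
for continuous variables.

The grid enumerates 3 × 17 = 51 cells, of which 49 are fitted and 2 are
structural skips, while the Bonferroni family defaults to the full 51
comparisons — a deliberately conservative family that matches how the
correction is conventionally stated for a 3-index × 17-outcome design; the
family size is a parameter. Evidence tiers: strong (p < α/family), nominal
(α/family ≤ p < α), null.

## Agreement

Spearman rho with average ranks (t-approximation p) on continuous totals;
weighted kappa on tertiles with linear (Cicchetti–Allison) disagreement
weights by default — the default of the statistical system this style of
analysis is usually run in — with quadratic weights available. Kappa
p-values are asymptotic tests of κ = 0 (via the large-sample variance in
`statsmodels`); a from-scratch observed/expected weighted-disagreement
oracle cross-checks the statistic in the tests.

## Synthetic cohort generator

The generator's defaults encode the cohort's published marginal structure:
BMI truncated-normal(47.5, 9.3) at ≥ 30 (weight is derived from BMI and
height so anthropometric identities hold); age a two-branch truncated
normal with P(age ≥ 50) = 0.66; activity zero-inflated (77.6% inactive)
lognormal; glycemic measures lognormal matched to the printed
median/IQR pairs; categorical frequencies as printed. Intake variables,
for which no cohort summaries are printed, use realistic adult-female
lognormal medians (e.g. vegetables 200 g/d, red meat 70 g/d, ethanol
median 8 g/d among the 55% who drink) with σ = 0.6; total energy is
lognormal(μ = 8.797, σ = 0.315), placing the ±3 SD log-energy rule on the
same kJ scale as the fixed bounds. Rank correlation ρ = 0.2 among intakes
is induced by a Gaussian copula. Item responses come from a per-domain
latent severity discretised at equal-interval thresholds, so planted domain
means are controllable.

What the generator does **not** emulate: the real joint distribution of
diet with demographics and outcomes (beyond the copula over intakes),
instrument-specific item wording effects, or any fitted association
magnitudes from real data. Passing tests therefore demonstrate that the
*machinery* (scoring, cascade, fitting, correction, agreement) is correct
and that planted effects are recovered without bias — not that the
synthetic cohort reproduces the real cohort's regression table.

`plant_effects` overwrites one outcome as intercept + β·z(exposure) +
covariate terms + Gaussian noise on the modelling scale (log scale for
glycemic outcomes); with zero noise the matching fit recovers β to 1e-8,
and over noisy replicates the empirical bias is within Monte-Carlo error of
zero (tested at 200–500 replicates; the coverage check uses 500 replicates
of an n = 150 cohort, sized to keep the default suite under a minute for
these tests while leaving Monte-Carlo error at ±1 percentage point of the
nominal 95%).

## Numerical choices and degenerate inputs

- z-scores: sample SD (n−1); a constant exposure raises.
- Quantiles: NumPy linear interpolation throughout.
- Boundary conventions are half-open and tested: MDS alcohol [5, 25) g/d,
  BMI bands [18.5, 25) and [25, 30), HADS bands as above, at-median → 1
  for beneficial MDS components, tertile boundary ties → lower tertile.
- Unscoreable records (missing BMI/activity/smoking where required) are
  flagged, never silently dropped; per-model complete-case analysis with
  reported n, no imputation.
- Pipeline runs are seeded end-to-end; the manifest records the config
  hash and SHA-256 of every output, and reruns are byte-identical.

## Known limitations

- The WCRF/EHLI cut-point tables are conventions, not a transcription of
  any specific study appendix; swap in exact tables via `CutpointConfig`.
- The FACIT reverse-scoring key must be supplied for a real instrument
  version; the default is structural only.
- The generator's independence assumptions (outside the intake copula)
  make bivariate tertile comparisons on synthetic data mostly null by
  construction.
- No imputation, mixed models or causal machinery; covariate sets are
  fixed configuration.
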