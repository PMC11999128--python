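# Methods

## The disease-progression model

Diabetes-mellitus progression is represented by a four-stage state
space crossing two clinical axes: whether the patient's HbA1c is within
a *personalized metabolic goal* (ON / OUT), and whether a *staging
chronic complication* — retinopathy, cerebrovascular disease, or
chronic kidney disease — has been diagnosed (NOT / YES). The four
stages, in the fixed ordering used for every matrix in the package, are
`ON-NOT, OUT-NOT, ON-YES, OUT-YES`.

Movement between ON and OUT is bidirectional (HbA1c fluctuates);
complications are absorbing, so the four cells `(ON-YES | OUT-YES) →
(ON-NOT | OUT-NOT)` of any transition matrix are structural zeros.
Every matrix the package produces or accepts is validated for
row-stochasticity (rows sum to 1 within 1e-9) and for those zeros;
observing a forbidden transition in data raises an error rather than
being silently repaired, since it indicates an upstream coding problem.

### Personalized goals

Guideline standards give three HbA1c thresholds (6.5, 7.0, 7.5 %)
"according to patients' characteristics" without a deterministic
mapping. The default `GoalPolicy` is an explicit operationalization:
age ≥ 65 or any staging complication → 7.5; age < 45 with no
complications → 6.5; otherwise 7.0. First matching rule wins and the
policy is fully configurable. "Within goals" is strict: HbA1c exactly
at the threshold is OUT. When a year carries several measurements the
last one is used (end-of-year status drives the next transition).

## Synthetic cohort generator

No real cohort ships with the package; the generator produces EHR-like
panels whose statistical structure matches the published reference
cohort, with complete ground truth so every downstream stage is
testable.

The generative model is a discrete-time four-state Markov chain at
one-year steps with stage-conditional emissions:

* **Initial distribution** — the reference cohort's 2018 stage
  occupancy (8,685 / 6,858 / 4,375 / 3,884 of 23,802 patients).
* **Transition kernels** — the published 1-year and 2-year matrices.
  The 2-year matrix is *not* the square of the 1-year matrix in the
  data, so both are kept: consecutive years step with the 1-year
  kernel, a 2-year gap steps with the 2-year kernel when supplied
  (chaining two 1-year draws otherwise). Printed rows sum to 99.99 /
  100.01 % due to rounding and are renormalized on load; this moves
  every cell by less than 0.01 pp.
* **Biomarkers** — per-stage normal draws with the reference
  means/SDs (age, LDL, eGFR, creatinine, BMI, weight, height, blood
  pressures), clipped to wide physiological ranges.
* **HbA1c** — truncated normal strictly below the personalized goal
  for ON stages and at/above it for OUT stages. The location parameter
  is solved numerically (cached per stage/threshold pair) so the
  *realized* stage-conditional mean equals the configured mean despite
  truncation; the realized SD is somewhat smaller than the configured
  SD, which is accepted.
* **Flags** — per-stage Bernoulli draws for patient compliance,
  professional HbA1c- and cholesterol-guideline adherence, and the four
  lifestyle-recommendation flags, at the reference prevalences.
  Adherence is *stated* in the note with probability 0.8 (free text
  does not always record it); when stated, the compliant/non-compliant
  split follows the stage prevalence.
* **Treatments** — the prescribed hypoglycemic class equals the
  guideline-ideal class exactly when the HbA1c-guideline flag is true,
  otherwise a different class (emulating treatment inertia /
  discordance); concrete drugs are drawn from the lexicon, including
  combination products. Antihypertensive counts are Poisson at the
  stage means; hypertension as a condition is present exactly when an
  antihypertensive is prescribed.
* **Complications** — on entering a YES stage one complication is
  sampled (kidney disease 0.60, retinopathy 0.25, cerebrovascular
  0.15 — kidney disease dominates incident complications in this
  population) and a corresponding ICD-10 code is written to the
  structured field from then on.

Notes are rendered from bilingual templates (Spanish-flavoured clinical
shorthand with English variants, stored in `data/templates.json`), one
sentence per entity, embedding a lexicon surface form for every
ground-truth entity. Noise knobs: misspelling rate (default 0.05) —
single-character edits guaranteed to be edit distance exactly 1 and
uniquely correctable back to the original token; abbreviation rate
(default 0.30) — conditions rendered as clinical abbreviations ("HBP",
"HTA", "ERC"); distractor rate (default 0.30) — filler phrases with no
lexicon content. A fraction of patient-years (default 0.30) has the
structured drug field blanked while the drugs remain in the note,
emulating the missingness that text extraction backfills.

What the generator does **not** emulate: real referral patterns,
free-text idiosyncrasies beyond the template family (negation scopes,
section headers, copy-forward), within-year HbA1c trajectories,
mortality/hospitalization/dropout, and covariate-dependent transitions
in its default mode. Passing tests therefore demonstrate correctness of
the pipeline mechanics and recoverability under the modeled noise, not
NLP performance on real clinical text.

### Planted effects

`PlantedEffects` switches path sampling to a bivariate logistic form:
the OUT-margin and (for NOT starters) the complication-margin of the
current stage's transition row are tilted on the logit scale by
configured coefficients on baseline binary covariates, then recombined
independently. This deliberately breaks the configured joint matrix —
it exists to create recoverable covariate effects for end-to-end
parameter-recovery tests of the prediction models, not to match
observed tables. Plain Markov mode is untouched.

## Text extraction

The extraction pipeline is deliberately simple and fully auditable:

1. **Preprocessing** — lowercase, accent folding, URL/digit/punctuation
   removal, stopword removal (bilingual list in the lexicon file),
   tokens shorter than 2 characters dropped. Idempotent on its own
   output.
2. **Spelling correction** — a token not in the lexicon vocabulary is
   replaced by the *unique* vocabulary token within Levenshtein
   distance 1 (computed with edlib); ties and misses leave the token
   unchanged. Corrections are memoized per lexicon.
3. **Dictionary search** — greedy longest-match n-gram scan (n ≤ 3,
   left to right, no overlaps), so combination products
   ("losartan hydrochlorothiazide") win over their components.
   Lemmatization/stemming is handled by surface-form enumeration in the
   lexicon (inflected/translated variants listed explicitly) rather
   than a language-specific stemmer — deterministic and bilingual-safe.
4. **Adherence polarity** — matched adherence phrases fire unless a
   negation term (`no, not, non, sin, niega, denies, without`) occurs
   within 4 tokens on either side of the span (span-internal tokens are
   ignored, so "no adherencia" is not self-negated). Negative patterns
   take precedence; no adherence span at all → `unstated`. This is
   rule-based by design, mirroring expert-validated patterns rather
   than a fitted classifier.
5. **Merging** — set-valued fields (drugs, conditions) take the union
   of structured and extracted values; scalar flags keep the structured
   value, and disagreements are logged with provenance.

The shipped lexicon covers every entity of the two worked-example
consultation notes plus the drug classes the guideline logic needs. Two
drugs visible in the first worked-example note (a corticosteroid and
aspirin) are deliberately absent from the lexicon because the published
derivation excludes them: lexicon scope, not extraction failure,
explains exclusions. The derived column's "Emagliflozin" is treated as
a typo for empagliflozin.

## Guideline adherence

Actual hypoglycemic class from the drug list: any insulin → `insulin`;
metformin + second-line agent (combination products expanded first) →
`combined`; metformin alone → `metformin`; else `none`. The ideal class
comes from an ordered band table over HbA1c and eGFR — default: HbA1c
< 8 and eGFR ≥ 30 → metformin; 8–9.5 → combined; > 9.5 or eGFR < 30 →
insulin — shipped as an explicit stand-in for the clinical-practice-
guideline algorithm, which is not published in full. The cross-tab of
ideal × actual is reported as counts and row percentages over treated
patients; the LDL threshold for the cholesterol-guideline flag defaults
to 100 mg/dL (reference LDL means sit near 93–97).

## Transition matrices

The 1-year matrix pools both adjacent-year pairs of the three-year
panel (the alternative — using only the first pair — discards half the
information; pooling is the package's choice where the source is
silent). The 2-year matrix uses the first-to-last pair. Counts are
row-normalized; unoccupied rows report zero proportions.

## Prediction models

Twelve nested binary tasks: per horizon (1, 2 years), a goal-outcome
model for each of the four stages, plus complication-outcome models for
the two NOT stages only (complications are absorbing, so predicting
them for YES starters is vacuous). Features are baseline-year values
only: demographics, biomarkers, treatment counts derived from the
(NLP-completed) drug list, and the adherence/recommendation flags.
Nothing measured at the horizon enters the matrix.

Training per task: stratified 80/20 train/test split (fixed seed);
grid search over nine learner families — KNN, logistic regression,
decision tree, random forest, gradient boosting, AdaBoost, LightGBM,
extra trees, and a feed-forward network — each with a small fixed
hyperparameter grid; 10-fold stratified cross-validation (folds reduced
automatically when the minority class is smaller); selection by mean CV
F1 with ties broken by AUC then accuracy; the winner is refit on the
full training split. Scaling (for KNN/logistic/network) lives inside
the estimator pipeline so folds are never contaminated.

The feed-forward network is implemented directly in numpy: three
fully connected hidden layers of 256 ReLU units, inverted dropout
(default rate 0.2) between layers, a sigmoid output, binary
cross-entropy + L2, minibatch Adam. Its grid varies L2 strength,
learning rate, and epochs. It follows the sklearn estimator protocol so
it sits in the same CV loops as the other families.

Resampling (off by default, matching the preference for the unresampled
models): SMOTE-style synthetic minority oversampling — new minority
points are convex combinations of a minority point and one of its k=5
nearest minority neighbors — either raising the minority to the
majority count, or moving both classes to an intermediate size
(default: the rounded mean of the class counts). Resampling applies to
training folds and the final training split only; the test split is
never touched.

**Cutoff** — predicted probabilities are binarized at the cutoff
maximizing Cohen's kappa, evaluated at 0, 1 and every midpoint between
adjacent distinct sorted probabilities; ties resolve to the smallest
cutoff. The cutoff is estimated on the training split and applied to
both splits' confusion rates (TPR/FPR/TNR/FNR).

**Marginal effects** — binary features are toggled 0→1; continuous
features are shifted by +1 sample SD (the perturbation size is a
package choice); the mean change in predicted probability over the
evaluation sample is reported in percentage points.

**Calculator** — for a NOT starter the goal-outcome probability `p_out`
and complication-outcome probability `p_comp` are combined into a
4-stage vector as an independent product,
`(1-p_out)(1-p_comp), p_out(1-p_comp), (1-p_out)p_comp, p_out·p_comp`;
for YES starters mass stays on the two YES stages. The independence
combination is a documented assumption — the nested decomposition never
specifies a joint rule.

No multiple-testing correction is applied across the twelve tasks; the
metrics are descriptive. AUC uses the mid-rank convention for ties;
single-class evaluation sets report AUC as missing, flagged.

## Inclusion filter

Patients must have an HbA1c value in every study year (applied first),
then complete values on all modeled predictors (no imputation). Removal
counts per rule are logged and reported.

## Numerical and testing choices

* All randomness flows from numpy `default_rng` seeded from the single
  configured seed; identical config ⇒ byte-identical cohort, report and
  metrics.
* Sample SDs use ddof=1; a single observation reports SD 0 with a
  warning rather than NaN.
* Combinatorial primitives (kappa cutoff, transition counting,
  cross-tab, dictionary search) are tested against independent
  brute-force oracles on randomized instances; generator calibration is
  tested by recovering the configured transition matrices within
  binomial sampling error at n = 20,000 (≈5,000 per row, binomial SE
  < 0.71 pp, tolerance 2 pp).
* Parameter-recovery tests use planted logistic effects of ±1.0–1.5 on
  the log-odds scale on the two adherence covariates, cohorts of 2,000
  patients, and a low-variance feature filter (variance > 0.01) before
  fitting — near-constant columns (e.g. the ~0.5 %-prevalence
  cholesterol-adherence flag) otherwise produce unstable coefficients
  that dominate marginal-effect rankings, which is the very behavior
  the prescribed variance/collinearity filter exists to remove.
  Multi-seed recovery loops label cohorts from ground-truth flags
  rather than re-running the (separately validated) NLP step, purely
  for speed.
* Desk-scale problem sizes (hundreds to a few thousand patients, the
  reduced logistic+tree grid) are used in the test suite; the full
  nine-family grid is exercised on one task. These sizes are the
  package's own defaults for its synthetic studies.

## Known limitations

* Table-level performance metrics of the original clinical study are
  properties of a proprietary cohort and are not reproduction targets;
  only the transition structure, the worked text examples and the
  >60 %-complication claim are.
* The goal policy, guideline band table and ICD-10 staging code list
  are documented stand-ins for unpublished clinical algorithms; all are
  configurable and user-replaceable.
* The generator's stage-conditional emissions are stationary across
  years (per-year drift is unreported in the source tables).
* The network probabilities are not calibrated before cutoff selection.
* The multinomial (single 4-class model) baseline is not implemented;
  the nested binary decomposition is the modeling strategy of record.
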