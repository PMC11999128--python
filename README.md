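# dmtransit

Modeling diabetes-mellitus progression as transitions between four
clinical stages, from EHR-like data that mixes structured fields with
free-text consultation notes.

Each patient-year is placed in one of four stages by crossing two axes:
whether HbA1c is within a *personalized metabolic goal* (`ON`/`OUT`,
thresholds 6.5/7.0/7.5 % by age and complication history, strict `<`)
and whether a *staging chronic complication* — retinopathy,
cerebrovascular disease, chronic kidney disease — has been diagnosed
(`NOT`/`YES`). Goal transitions are bidirectional; complications are
absorbing, giving the transition matrix

```
            ON-NOT  OUT-NOT  ON-YES  OUT-YES
ON-NOT        .       .        .       .
OUT-NOT       .       .        .       .
ON-YES        0       0        .       .
OUT-YES       0       0        .       .
```

with structural zeros in the lower-left block. On top of the staging
the package provides, end to end:

* **`dmtransit.cohort`** — a synthetic EHR generator: a four-state
  Markov chain at one-year steps with stage-conditional emission of
  biomarkers, drug lists and bilingual clinical notes, calibrated to a
  published reference cohort's per-stage distributions and 1-/2-year
  transition matrices, with full ground truth for every patient-year.
* **`dmtransit.nlp`** — dictionary-based note extraction: normalize,
  correct spelling within edit distance 1, greedy longest-match search
  over a curated medical lexicon, rule-based adherence polarity with a
  negation window, and backfill of missing structured fields.
* **`dmtransit.staging`** — goal policies, stage assignment, absorbing
  complication status from ICD-10 codes, and 1-/2-year transition
  matrices with structural-zero validation.
* **`dmtransit.adherence`** — ideal-vs-prescribed hypoglycemic
  treatment classes (`metformin`/`combined`/`insulin`) and the 3×3
  prescribing-concordance cross-tabulation, before and after NLP
  backfill.
* **`dmtransit.models`** — twelve nested binary transition-prediction
  tasks (goal outcome per stage and horizon; complication outcome for
  complication-free starters), a nine-family model grid with stratified
  10-fold CV and F1 selection, optional SMOTE-style resampling of
  training folds, Cohen's-kappa-optimal probability cutoffs,
  per-feature marginal effects in percentage points, and a calculator
  that combines the two nested models into a 4-stage probability
  vector.
* **`dm-transit`** (CLI) — `simulate`, `label`, `stage`, `adherence`,
  `transitions`, `train`, `predict`, and `run` for the full pipeline
  from one YAML config.

Who it is for: biostatisticians and health-services researchers who
want a tested, reproducible scaffold of this staging-and-prediction
workflow — to study its behavior under controlled synthetic conditions,
or to point the same pipeline at their own patient-year table and
lexicon.

## Worked example

```python
from dmtransit import (
    CohortConfig, generate_cohort, label_cohort, stage_cohort,
    summarize_transitions, Stage,
)

config = CohortConfig(n_patients=1000, seed=42)   # defaults = reference-cohort structure
records, truth = generate_cohort(config)          # EHR-like table + ground truth
labeled, _ = label_cohort(records)                # NLP labels + backfill
staged = stage_cohort(labeled)                    # four-stage assignment
matrices = summarize_transitions(staged, horizons=[1, 2])
print(matrices[1].to_frame(percent=True).round(2))

m2 = matrices[2]
frac = m2.cell(Stage.ON_NOT, Stage.ON_YES) + m2.cell(Stage.ON_NOT, Stage.OUT_YES)
print(f"ON-NOT starters with complications after 2 years: {100*frac:.1f}%")
```

prints

```
         ON-NOT  OUT-NOT  ON-YES  OUT-YES
ON-NOT    44.69     9.34   37.36     8.61
OUT-NOT   15.85    41.96   13.17    29.02
ON-YES     0.00     0.00   82.32    17.68
OUT-YES    0.00     0.00   25.87    74.13

ON-NOT starters with complications after 2 years: 69.6%
```

Row *i*, column *j* is the percentage of patients starting the year in
stage *i* that end it in stage *j*, pooled over both adjacent-year
pairs of the three-year panel. At n = 1,000 the recovered matrix sits
within sampling error of the configured 1-year kernel (e.g. 44.7 %
of within-goal, complication-free patients stay put vs the configured
47.8 %), the lower-left block is exactly zero, and — the substantive
point — most patients who start in the best stage nonetheless occupy a
complication stage two years later.

The same run from the shell:

```bash
dm-transit run --config src/dmtransit/data/default_config.yaml --out-dir out/
```

writes `cohort.csv`, `truth.jsonl`, `labeled.csv`, `staged.csv`,
`transitions.json`, `model_metrics.json` and a human-readable
`report.md`.

## Layout

```
src/dmtransit/
  stages.py     state space, matrix validation, reference matrices
  cohort.py     synthetic cohort generator + note renderer
  nlp.py        lexicon, preprocessing, search, adherence, merging
  staging.py    goal policy, stage assignment, transition matrices
  adherence.py  treatment classes, guideline bands, cross-tabs
  models.py     the 12 prediction tasks, grids, cutoffs, effects
  neural.py     3x256 ReLU + dropout feed-forward classifier
  pipeline.py   orchestration, filtering, reporting
  cli.py        dm-transit command group
  data/         lexicon, templates, drug classes, ICD-10 map, config
docs/methods.md   model assumptions, parameters, design choices
```

See `docs/methods.md` for the full account of the generative model,
the extraction rules, the staging and guideline conventions, and the
numerical choices.
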