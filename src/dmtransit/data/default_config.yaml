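# Default pipeline configuration.
#
# The cohort block reproduces the reference study conditions: a
# three-year panel, the observed stage-conditional biomarker
# distributions and flag prevalences (built-in defaults), the observed
# 1- and 2-year transition matrices, and the 2018 initial stage
# distribution. Omitted cohort fields fall back to those calibrated
# defaults; the matrices and initial distribution are spelled out here
# so the file documents them.
cohort:
  n_patients: 2000
  years: [2018, 2019, 2020]
  seed: 0
  initial_stage_probs: [0.36489, 0.28813, 0.18381, 0.16317]
  transition_matrix_1y:
    - [0.47754775, 0.10101010, 0.34623462, 0.07520752]
    - [0.16109389, 0.40815918, 0.11968803, 0.31105889]
    - [0.0, 0.0, 0.8184, 0.1816]
    - [0.0, 0.0, 0.2694, 0.7306]
  transition_matrix_2y:
    - [0.2686, 0.0673, 0.5204, 0.1437]
    - [0.11571157, 0.21032103, 0.22332233, 0.45064506]
    - [0.0, 0.0, 0.8099, 0.1901]
    - [0.0, 0.0, 0.3298, 0.6702]
  note_noise:
    misspelling_rate: 0.05
    abbreviation_rate: 0.30
    distractor_rate: 0.30
horizons: [1, 2]
train:
  fast: true
  resampling: none
  seed: 0
log_level: INFO
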