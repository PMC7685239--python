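# Single-ascending-dose rich-sampling trial, OAB, 5-<18 y.  Each subject
# receives one dose of three times the weight-adjusted PED (cohorts at
# PED2.5, PED5 or PED10) of the alternate formulation, with a rich
# sampling grid out to 72 h.  The grid itself is a simulator default.
trial:
  name: giraffe
  study: GIRAFFE
  population: OAB
  strata:
    - label: children
      age_range: [5, 12]
      n: 28
      weight_mean: 29.32
      weight_sd: 8.65
      weight_floor: 14.0
    - label: adolescents
      age_range: [12, 18]
      n: 14
      weight_mean: 55.70
      weight_sd: 14.42
      weight_floor: 32.0
  agp_median: 67.0
  agp_sdlog: 0.25
  titration_weeks: []
  pk_visit_weeks: []
  duration_weeks: 1
  sampling_windows: []
  single_dose: true
  dose_multiplier: 3.0
  single_dose_levels: [2.5, 5.0, 10.0]
  rich_grid: [0.5, 1, 2, 3, 4, 6, 8, 12, 24, 48, 72]
  lloq: 0.2
  uloq: 200.0
  formulation: B
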