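# 12-week placebo-controlled titration trial, OAB, 5-<18 y.
# PK at week 12: pre-dose within 3 h, post-dose windows 1-3, 4-5 and
# 7-10 h, plus a washout sample 2-3 days after the last dose.
trial:
  name: lion
  study: LION
  population: OAB
  strata:
    - label: children
      age_range: [5, 12]
      n: 73
      weight_mean: 29.32
      weight_sd: 8.65
      weight_floor: 14.0
    - label: adolescents
      age_range: [12, 18]
      n: 22
      weight_mean: 55.70
      weight_sd: 14.42
      weight_floor: 32.0
  agp_median: 67.0
  agp_sdlog: 0.25
  titration_weeks: [3, 6, 9]
  pk_visit_weeks: [12]
  duration_weeks: 12
  sampling_windows:
    - [predose, -3, 0]
    - [early, 1, 3]
    - [mid, 4, 5]
    - [late, 7, 10]
  washout_window: [48, 72]
  titration: {p_up: 0.63, p_down: 0.03}
  lloq: 0.2
  uloq: 200.0
  formulation: A
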