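# 52-week open-label titration trial, NDO, 6 months-<5 y.  Starting dose
# PED2.5 below age 2, PED5 otherwise; PK at one visit among weeks 12/24/36
# with pre-dose within 3 h and post-dose windows 1-3, 4-5 and 7-10 h.
# Weights follow a piecewise-linear age->median curve (simulator default).
trial:
  name: marmoset
  study: MARMOSET
  population: NDO
  strata:
    - label: young_children
      age_range: [0.5, 5]
      n: 37
      age_weight_curve:
        - [0.5, 7.8]
        - [1.0, 9.6]
        - [2.0, 12.2]
        - [3.0, 14.3]
        - [4.0, 16.3]
        - [5.0, 18.3]
      weight_cv: 0.13
      weight_floor: 5.0
  agp_median: 67.0
  agp_sdlog: 0.25
  start_level: 5.0
  start_level_under2: 2.5
  titration_weeks: [3, 6, 9, 12]
  pk_visit_weeks: [12, 24, 36]
  duration_weeks: 52
  sampling_windows:
    - [predose, -3, 0]
    - [early, 1, 3]
    - [mid, 4, 5]
    - [late, 7, 10]
  titration: {p_up: 0.63, p_down: 0.03}
  lloq: 0.2
  uloq: 200.0
  formulation: A
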