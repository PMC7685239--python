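# 52-week open-label titration trial, NDO, 5-<18 y.  Titration every 3
# weeks for up to 12 weeks; PK at one visit among weeks 12/24/36 with
# pre-dose within 3 h and post-dose windows 1-3, 4-6 and 7-10 h (four
# samples).  Weight distributions are simulator defaults (slightly below
# the OAB trial to reflect reduced muscle mass in neurogenic bladder).
trial:
  name: monkey
  study: MONKEY
  population: NDO
  strata:
    - label: children
      age_range: [5, 12]
      n: 42
      weight_mean: 27.0
      weight_sd: 8.0
      weight_floor: 13.0
    - label: adolescents
      age_range: [12, 18]
      n: 20
      weight_mean: 50.0
      weight_sd: 13.0
      weight_floor: 30.0
  agp_median: 67.0
  agp_sdlog: 0.25
  titration_weeks: [3, 6, 9, 12]
  pk_visit_weeks: [12, 24, 36]
  duration_weeks: 52
  sampling_windows:
    - [predose, -3, 0]
    - [early, 1, 3]
    - [mid, 4, 6]
    - [late, 7, 10]
  titration: {p_up: 0.63, p_down: 0.03}
  lloq: 0.2
  uloq: 200.0
  formulation: A
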