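# Methods

`pedpk` implements a population-pharmacokinetic analysis of solifenacin in
pediatric patients with overactive bladder (OAB) or neurogenic detrusor
overactivity (NDO): compartmental structural models, a covariate model
(fat-free mass, α1-acid glycoprotein, CYP3A4 ontogeny), a clinical-trial
simulator with dose titration, a Laplace nonlinear mixed-effects estimator,
and dose-normalized exposure summaries. Because the patient-level trial
data are not publicly deposited, the simulator is the package's data
source: its defaults encode the published trial designs and demographics,
and the estimator is validated by simulate-and-refit experiments and by
analytic oracles.

## Structural models

Two structural models are supported, both with first-order oral absorption
and an absorption lag time:

- **One-compartment** (sparse NDO designs): parameters CL/F, V/F, ka, ALAG.
- **Two-compartment** (OAB design pooled with rich single-dose data):
  CL/F, V2/F, Q/F, V3/F, ka, ALAG, plus a relative bioavailability F1 for
  the alternate formulation.

Concentrations are closed-form sums of exponentials in the shifted time
`t − ALAG`. The micro constants are `k10 = CL/V2`, `k12 = Q/V2`,
`k21 = Q/V3`; the hybrid disposition rates λ1 ≥ λz are the roots of
`λ² − (k10+k12+k21)λ + k10·k21 = 0`, with the small root computed from the
product `λz = k10·k21/λ1` to avoid cancellation. Units are fixed
throughout: doses mg (of solifenacin succinate as labeled), time h,
volumes L, concentrations ng/mL; the mg/L → ng/mL factor 1000 is applied
exactly once.

**Degenerate absorption.** When `|ka − λ| < 1e-8·λ` for any disposition
rate the exponential pair collapses; the limiting `t·exp(−λt)` form is
used instead of dividing by a near-zero difference. The same limit is
propagated through the steady-state accumulation algebra
(`Σ (t+nτ)·r^n` has a closed form in `r = exp(−λτ)`).

**Steady state.** Once-daily steady-state profiles use per-exponential
geometric accumulation `1/(1−exp(−λτ))`, which equals the infinite
superposition limit; inside the lag window (`t ≤ ALAG`) the profile is fed
by previous doses only, so those times are mapped forward by one interval.
Times past τ are interpreted as time since the final administered dose,
which also gives post-treatment washout profiles. A test requires the
shortcut to agree with explicit 30-dose superposition to < 0.1%.

**Secondary metrics** (per subject, at the steady-state dose):
`t1/2 = ln 2/λz`, `Vz/F = CL/F ÷ λz`, `AUC/D = F1/(CL/F)` (equal to both
AUC(0–∞) of a unit dose and the steady-state AUC over one interval per
unit dose, for linear kinetics — verified against trapezoidal integration
to 10 half-lives plus `Clast/λz` extrapolation), Ctrough at `t = τ`, and
Cmax/tmax by bounded scalar minimization on `(ALAG, τ]` with a 1e-4 h
tolerance (the two-compartment tmax has no closed form).

## Covariate model

Individual typical parameters are power functions of fat-free mass (FFM)
and AGP relative to reference covariates (FFM 24 kg, AGP 67):

```
CL/F = θ_CL (FFM/24)^0.652 (AGP/67)^−0.649 · [1 − f_CYP(1 − mat(age))]
V2/F = θ_V2 (FFM/24)^1.18  (AGP/67)^−1.06
V3/F = θ_V3 (FFM/24)^1.07
```

with `θ_CL = 8.81 L/h`, `θ_V2 = 162 L`, `θ_Q = 98.1 L/h`, `θ_V3 = 174 L`,
`ka = 0.742 /h`, `ALAG = 0.834 h`, `F1 = 1.12` in the shipped `lion_final`
configuration. Q/F carries no covariates. AGP is treated strictly as a
ratio to the reference level so that inconsistent unit annotations in the
source tables cancel; the package never interprets its absolute scale.

**CYP3A4 ontogeny** (relevant below ~2 years of age) is a Hill function of
postnatal age, `mat(age) = age^h/(age^h + TM50^h)`, applied to the
CYP3A4-mediated fraction `f_CYP` of clearance. The published analysis
cites an ontogeny function without printing it, so the defaults here are
package choices: `TM50 = 0.3 y`, `h = 2` (≈98% maturation by age 2,
matching the assumption of complete maturation for subjects ≥ 2 y) and
`f_CYP = 0.8` (solifenacin is predominantly CYP3A4-metabolised). All three
are configurable; they are declared defaults, not estimates.

**Inter-individual variability** is log-normal on CL/F, V2/F (or V/F) and
ka: each parameter is multiplied by `exp(η)`, `η ~ N(0, ω²)`. The source
analysis does not print ω or σ estimates, so the simulation defaults are
package choices: ω = {CL 0.35, V 0.45, ka 0.5} (log-scale SD) and residual
σ = {proportional 0.20, additive 0.05 ng/mL}, selected so simulated
exposure CVs land in the observed 33–58% range. Residual error is
combined, `y = f(1+ε_p) + ε_a`, with negative draws floored at zero and
flagged.

**Pediatric equivalent doses (PED).** The trials dosed by body size to
match adult steady-state exposure at 2.5/5/7.5/10 mg. The actual dosing
tables are not published; the default rule scales the adult dose by
`(FFM/52 kg)^0.652` — the clearance exponent, making typical steady-state
AUC size-independent by construction — and rounds to 0.5 mg (1 mg/mL
suspension). An explicit band table can be supplied as data.

**FFM imputation** for synthetic subjects uses
`FFM = weight·(0.85 − 0.003·max(age−5, 0))`, a simple declining fat-free
fraction; real datasets must carry FFM explicitly.

## Trial simulator

Four shipped presets mirror the published designs:

| preset | population | ages | length | PK sampling |
|---|---|---|---|---|
| `lion` | OAB | 5–<12, 12–<18 y (n = 73 + 22) | 12 wk | week 12: pre-dose (−3–0 h), 1–3, 4–5, 7–10 h, washout 48–72 h after last dose |
| `monkey` | NDO | 5–<12, 12–<18 y (n = 42 + 20) | 52 wk | one of weeks 12/24/36: pre-dose, 1–3, 4–6, 7–10 h |
| `marmoset` | NDO | 0.5–<5 y (n = 37) | 52 wk | one of weeks 12/24/36: pre-dose, 1–3, 4–5, 7–10 h |
| `giraffe` | OAB | 5–<18 y (n = 42) | single dose | rich grid 0.5–72 h |

Subjects start at PED5 (PED2.5 below age 2) and titrate every 3 weeks, one
level at a time on the 2.5/5/7.5/10 ladder, until the design's last
titration week. The published per-visit dryness rates are not available,
so the Bernoulli titration policy is calibrated, not estimated: with
`p_up = 0.63` (up-titrate when not dry) and `p_down = 0.03` (bothersome
event) the simulated share on PED10 at week 12 is ≈66%, consistent with
the reported 64–73% across age groups. Weight distributions use the
published means/SDs where printed (OAB children 29.32 ± 8.65 kg,
adolescents 55.70 ± 14.42 kg), truncated at ±2.5 SD and a per-stratum
floor; the NDO trials' demographics are not printed, so their defaults
(children 27 ± 8 kg, adolescents 50 ± 13 kg; infants from a
piecewise-linear age→weight curve with 13% CV) are package choices. AGP is
log-normal around the reference (median 67, log-SD 0.25). The single-dose
design doses 3× the PED (ascending cohorts at PED2.5/5/10) of the
alternate formulation; its rich grid {0.5, 1, 2, 3, 4, 6, 8, 12, 24, 48,
72} h is a package default. Dosing-time jitter is available but off by
default.

Observations below the assay lower limit (0.2 ng/mL; range 0.2–200) are
flagged and their values withheld (M1 handling: excluded from fitting; the
flag is retained so a censored-likelihood extension remains possible).
Output is a NONMEM-format rectangular CSV (ID, TIME, TAD, AMT, DV, EVID,
MDV, BLQ, PED, WEEK, AGE, WT, FFM, AGP, STUDY, FORM; missing cells `.`),
written losslessly (shortest exact decimal representation).

What the simulator does **not** emulate: dropout and adherence, efficacy
outcomes beyond the Bernoulli titration driver, longitudinal AGP change,
assay error structure beyond combined additive+proportional noise, or
between-site heterogeneity. Passing tests therefore demonstrate
correctness of the pipeline under the declared generative model, not
agreement with any real patient's data.

## Estimation

The marginal likelihood over the subject-level random effects is
approximated by the Laplace method at the per-subject conditional mode
(the interaction variant: residual variance depends on the individual
prediction). For subject *i* with data part
`d(η) = Σ_j [log 2πv_j + (y_j − f_j)²/v_j]`, the objective contribution is

```
−2 log L_i ≈ d(η*) + η*'Ω⁻¹η* + log|Ω| + log|½∇²d(η*) + Ω⁻¹|
```

- **Inner problem**: the mode η* is found by damped Newton with the exact
  gradient (including the ∂v/∂η interaction term) and a Gauss–Newton
  search curvature `2J'V⁻¹J + 2Ω⁻¹`; the Jacobian J is central
  finite-difference. Gradient tolerance 1e-8, warm-started from the
  previous outer iteration; a quasi-Newton fallback handles the rare
  non-converging subject. On linear-Gaussian models this machinery is
  exact, which is tested against the closed-form marginal normal
  likelihood to 1e-6.
- **Curvature term**: the Hessian of the data part at the mode is central
  finite-difference (relative step 1e-4); the prior contribution Ω⁻¹ is
  added analytically, so the ω → 0 limit collapses cleanly to the
  extended-least-squares deviance (tested to 1e-4).
- **Outer problem**: all positive parameters (θ, ω, σ) are searched on the
  log scale (estimated covariate exponents untransformed) with L-BFGS-B by
  default (Nelder–Mead and Powell available). Standard errors come from
  the inverse numerical Hessian of the objective at the optimum
  (covariance `2H⁻¹`), delta-mapped to the natural scale.
- **Empirical Bayes**: per-subject η modes at the final estimates;
  shrinkage reported as `1 − SD(η*)/ω`. Subjects with no quantifiable
  observations are excluded with a log entry.

The η dimension is capped at the three parameters the final models carry
(CL, V2 or V, ka), with no η covariance by default. Requesting a
two-compartment fit on a sparse design (median < 6 observations/subject)
raises a warning, since the profile shape is then not identifiable — the
sparse NDO designs are fitted with the one-compartment model.

**Validation by recovery.** With patient data unavailable, the estimator
is validated the way the original analysis logic implies: simulate 100
subjects under the `lion_final` typical values on the rich single-dose
design (ω and σ at the simulation defaults), refit the five structural
fixed effects plus three ω and σ from scratch, and repeat over 5 seeds.
Acceptance requires median CL/F and V2/F errors < 15% and ka < 30%;
typical runs land near 5%/6%/14%. The problem size (100 subjects, 11
samples each, 5 seeds) keeps a full recovery run in the minutes range on
one core.

## Exposure summaries

Per-subject metrics (AUC/D, Cmax/D, Ctrough/D, tmax, t1/2, CL/F, Vz/F) are
derived from the empirical-Bayes parameters at the dose received at PK
sampling; "/D" metrics divide by that dose. Groups are summarised by
geometric mean and geometric CV% — exactly
`exp(mean(log x))` and `sqrt(exp(sd(log x)²) − 1)·100` with the n−1 sample
SD — except tmax, reported as median (range). Dosing tables report n (%)
per visit × dose level × age group with percentages of the stratum
denominator rounded half-up to one decimal.

Exposure is classified against the adult 10 mg suspension reference
(target steady-state AUC 889 ng·h/mL, 5th–95th percentile 421–1896).
Membership uses the closed interval, and the comparison is made on AUC
scaled to the PED10-equivalent dose (`AUC/D × PED10 dose`), since the
reference derives from 10 mg in adults; whether the original analysis
normalised this way is not stated, so the choice is declared here.

## Numerical and design notes

- One pipeline seed is split into per-stage substreams (hash-derived
  `SeedSequence` children), so stages are independently reproducible and a
  fixed seed yields byte-identical artifacts.
- Configs are strict: unknown YAML keys are rejected before any
  computation.
- `exp(η)` is clamped at |η| ≤ 40 inside the predictor; such values are
  reachable only by optimizer probes, never by the prior.
- Eigenvalue floors (1e-10) guard the log-determinant when
  finite-difference noise makes the curvature indefinite.
- Degenerate inputs rejected with named errors: non-positive rates or
  volumes, FFM > weight, observations preceding any dose, rows carrying
  both a dose and an observation.

## Known limitations

- The likelihood approximation is Laplace/FOCE-I-class; no SAEM or
  importance-sampling refinement, no η covariance estimation, no M3
  censored likelihood (below-limit rows are excluded).
- Covariate exponents are fixed at their published values by default;
  they can be estimated, but the rich-sampling recovery experiment does
  not exercise that path.
- The ontogeny function's parameters and the PED dosing bands are
  declared package defaults where the source did not print them; analyses
  sensitive to these should supply their own configuration.
- Standard errors assume a locally quadratic objective; no bootstrap or
  sampling-importance-resampling alternative is provided.
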