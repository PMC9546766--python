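# Methods

## The model being validated

The subject of the package is a multinomial logistic model for the absolute
risk, at a fixed horizon τ (2 or 4 years), of the nine mutually exclusive
outcome *sequences* a patient with advanced CKD can follow among kidney
replacement therapy (KRT), a first cardiovascular event (CVD) and death.
With "no event" as the reference category,

    LP_k = α_k + Σ_j β_kj · t_j(x_j)                     k = 1..8
    P(no event) = 1 / (1 + Σ_k exp LP_k),    P(k) = exp(LP_k) · P(no event)

Predictors are age, sex, race, CVD history, diabetes, current smoking,
systolic blood pressure, eGFR and urine ACR. Transforms t_j are declarative
(identity or natural log, then a centering offset and scaling divisor,
in that order), so coefficient sets are pure data: the engine makes no
assumption beyond the YAML schema. The softmax is evaluated with
log-sum-exp stabilisation; the nine probabilities sum to 1 within 1e-12 by
construction and this is asserted on every vector. The packaged
`example_multinomial_synthetic.yaml` is an invented, clearly labelled
demonstration coefficient set — qualitatively sensible but not any
published model; users validating a published calculator supply its
transcribed coefficient file.

Combined endpoints are fixed sums of sequence probabilities (any KRT, any
CVD, death, death without KRT, death after KRT, no event). They are not
mutually exclusive and need not sum to 1; the identity
death = death-without-KRT + death-after-KRT is exact and tested.

Two published auxiliary equations ship as data:

- **KFRE** (4-variable, 2-year): risk = 1 − S₀^exp(Σ β_j (t_j(x_j) − c_j))
  with S₀ = 0.9832 and the published centering constants.
- **PCR→ACR crosswalk**: a piecewise-linear spline in ln(PCR) with knots at
  50 and 500 mg/g plus female/diabetes/hypertension indicators, applied
  only when ACR is missing and PCR measured — a measured ACR is never
  overridden. The conversion needs a hypertension flag, which the cohort
  schema therefore carries as an optional column; when absent, a
  configurable default (hypertensive) is used, reflecting the target
  population's ~89% prevalence.

## Outcome classification

A raw history (krt_time, cvd_time, death_time, censor_time; years from
baseline; exactly one terminal boundary per subject) is classified at a
horizon with these conventions:

- the horizon interval is closed: an event at exactly τ counts;
- ties: an event at exactly the death time is counted as preceding death
  (KRT = death ⇒ "death after KRT"); a KRT/CVD tie puts KRT first. The
  ordering is arbitrary but fixed, for reproducibility;
- only the first CVD event is modelled;
- a subject neither dead nor followed to τ is "censored before horizon"
  and has no category — even if some events were observed before
  censoring, since the full sequence by τ is unknown. (Consequently a
  first-event risk set can count an event for a subject whose sequence
  category is undefined; the cross-module test states the agreement in
  exactly this form.)

Classification is validated against an independently written brute-force
rule table over all presence patterns × time orderings on a grid.

## Observed risk: Aalen–Johansen

The estimator is the standard product-limit generalisation: at each event
time, CIF_k jumps by S(t⁻)·d_k(t)/n(t) and S multiplies by
(1 − Σ_k d_k(t)/n(t)). Events precede censorings at tied times. Step
functions are right-continuous and horizon evaluation is inclusive.
Conservation (Σ CIF + S = 1 at every jump, tolerance 1e-10), the
Kaplan–Meier reduction in the single-cause limit, and agreement with
lifelines' estimator serve as oracles. Variance estimation is out of scope.

Each combined endpoint induces its own first-event coding (for "any KRT":
event = KRT start, competing = death before KRT, CVD ignored; etc.). For
the "no event" endpoint we use the composite first-event coding with the
predicted event-free probability entering concordance negated; the source
analysis does not state its coding for this endpoint, so ours is a
documented choice, recorded in the report output's `coding` column rather
than asserted as the original's.

## Discrimination

The competing-risks concordance keeps subjects with a competing event in
the comparison as "never experiences the event" comparators. After
truncating everything at τ (later events recoded as censored at τ), a pair
(i, j) with i experiencing the event of interest at T_i is comparable iff
j has a competing event (any time), or j's event/censoring time is
strictly after T_i. Concordance means pred_i > pred_j; prediction ties
count ½; pairs with both events at the same time are not comparable.
Properties tested: exact equality with a literal brute-force pair
enumeration (1,000 random instances), exact reduction to Harrell's C on
competing-event-free data (against lifelines), and invariance under
strictly monotone transforms of the predictions. When no pair is
comparable the result is an explicit undefined-result signal, never a
number.

Binary AUC (for the eight sequence-level sensitivity analyses) is the
Mann–Whitney statistic via ranks, cross-checked against scikit-learn.

## Calibration and uncertainty

Calibration-in-the-large is (mean predicted risk, Aalen–Johansen incidence
at τ). Grouped calibration ranks subjects by predicted risk into
near-equal groups (deciles by default; remainder spread over the
lowest-risk groups) and estimates each group's observed risk by
within-group Aalen–Johansen. A lowess line (local linear, span 2/3) is
available as a display smoother only; the decile points are the tested
surface.

Confidence intervals are percentile bootstrap (default B = 2000, seeded;
replicates on which the statistic is undefined are dropped, and more than
50% undefined aborts the interval). The bootstrap's coverage is itself
tested by simulation (mean of n = 200 normals, 500 Monte-Carlo
repetitions, B = 400: observed coverage within 2 points of 95%). Wilson
score intervals are used for diagnostic proportions.

## Decision analysis

Referral rules use strict inequalities — risk > cutoff, eGFR < cutoff —
matching how such guideline thresholds are printed; an OR-composite covers
the "risk > 50% and/or eGFR < 15" guideline. The 1-year outcome is
KRT initiation within the window; death or censoring inside the window is
outcome-negative (censoring is deliberately not modelled here, mirroring
the acknowledged simplification of such clinical-impact projections; over
a 1-year window the distortion is small). Net benefit is
TP/n − (FP/n)·p_t/(1−p_t) over a default grid p_t = 0.01…0.50 step 0.01 —
interpretation degrades at extreme thresholds — with treat-all and
treat-none references (treat-none ≡ 0; treat-all crosses zero exactly at
the outcome prevalence, an identity the tests assert). Because each rule's
flags are fixed, its curve varies over the grid only through the
false-positive weight.

Integer-percent reporting rounds halves away from zero (76.50% → 77%).

## Synthetic cohort generator

The generator defines the study conditions for every stochastic test; its
defaults are fixed and not tuned per test.

**Covariates.** Age ~ truncated normal on [65, 100] (sd 8; location
74.9301 solved so the *population median* is exactly 76 years); male 66%,
black race 1.3%, CVD history 39.7%, diabetes 42.3%, current smoker 9.0%,
hypertension 89.2%; SBP ~ N(143, 22²) mmHg; eGFR ~ N(18, 4²) truncated to
the [10, 30] ml/min/1.73 m² inclusion window (the truncated mean is
therefore ≈ 18.20, which the tests account for); ACR log-normal with
median 391 mg/g and log-sd 2.456 (set from the reported interquartile
range 57–1566 mg/g), clipped to [1, 25000]. One child random stream per
subject is spawned from the master seed, so cohorts are prefix-stable in n.

**Events.** First events are competing exponentials with cause-specific
proportional hazards λ_k(x) = λ0_k · exp(β_k · z) over standardised
covariates (continuous: configured location/scale; ACR on the log scale;
binary: (x − p)/√(p(1−p))). After a non-death first event the remaining
hazards are multiplied by post-event modifiers (death ×1.6 after KRT,
×2.2 after CVD, compounding multiplicatively when both occurred; KRT ×1.3
after CVD and vice versa) and the clock restarts. Death absorbs.
Administrative censoring is uniform on [1, 6] years. Default log hazard
ratios are moderate and clinically signed (KRT driven down by eGFR and up
by albuminuria; death driven by age); baseline rates
λ0 = (0.0978, 0.1044, 0.0728)/yr were calibrated once, analytically via
the oracle's mean combined risks over a large covariate sample, so the
2-year marginal any-KRT / any-CVD / death proportions sit at
0.196 / 0.204 / 0.204 — the order of magnitude reported for the target
population (the resulting 2-year event-free fraction is ≈ 0.52 and the
4-year ≈ 0.30, likewise in line). These marginals are descriptive
calibration, not an acceptance surface.

**Oracle.** Given covariates all hazards are constant, so the semi-Markov
restart is immaterial and the process is a 9-state continuous-time Markov
chain (baseline; KRT; CVD; KRT→CVD; CVD→KRT; four absorbing death states
by history). The exact sequence probabilities at τ are row 0 of
exp(Qτ), computed with scipy's matrix exponential — exact for every
covariate pattern, with no equal-rate degeneracies to special-case — and
verified against a 150,000-replicate Monte-Carlo frequency table (3 MC
standard errors per category) and against closed forms in the degenerate
single-cause cases.

**What the simulator does not emulate.** Real cohorts have missing data
(the package rejects incomplete covariates rather than imputing),
informative censoring, country/centre effects, repeated longitudinal
measurements, and covariate-dependent censoring; hazards here are constant
in time given covariates. Passing the parameter-recovery tests therefore
shows the *metrics* are correct and the pipeline coherent — not that any
particular published model is well calibrated on real data.

## Problem sizes and numerical choices

End-to-end parameter recovery runs at n = 50,000 (decile Monte-Carlo bands
of 3.5 binomial standard errors; calibration-in-the-large tolerance 0.01);
the simulator's closed-form first-event check uses n = 50,000 against the
binomial 99% interval; generator location checks use n = 20,000; the
concordance-oracle sweep uses 1,000 instances of n ≤ 30 (brute force is
quadratic); concordance on large cohorts is reported on a 4,000-subject
prefix subsample. Probability-sum tolerances: 1e-12 (multinomial), 1e-10
(Aalen–Johansen conservation), 1e-8 (oracle rows after clipping
renormalisation). Tie-breaking choices are listed with each estimator
above. Degenerate inputs yield explicit undefined flags (diagnostics with
empty denominators, concordance with no comparable pairs, single-class
AUC) rather than fabricated numbers.

## Known limitations

- The published multinomial coefficient matrix is not bundled; the engine
  is deliberately coefficient-agnostic and ships only a synthetic example.
  A cross-check table against the public web calculator is a manual
  procedure, not an automated test.
- The PCR→ACR coefficients are transcribed as shipped data; the functional
  form and monotonicity are tested, the transcription itself is data.
- No variance estimation for cumulative incidence curves; no Fine–Gray
  regression; no time-dependent AUC or Brier scores.
- Decision-analysis confidence intervals are Wilson score by choice and
  labelled as such in the output.
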