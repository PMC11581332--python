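# Methods

This note documents the statistical machinery in `hrqolseg`: the models,
their assumptions, the defaults and why they were chosen, and what the
synthetic cohort does and does not emulate.

## Quartile segmentation

**Model.** For each HRQoL instrument `y` (EQ-5D index, VAS; both on
0–100), three conditional quantile surfaces are fitted at
τ ∈ {0.25, 0.5, 0.75}:

    Q_τ(y | x) = β₀(τ) + β₁(τ)·age + β₂(τ)·duration

with age in years and duration = years since MS diagnosis, both at the
time of the HRQoL assessment. Each τ is fitted **independently** by
minimising the pinball loss Σᵢ ρ_τ(yᵢ − xᵢᵀβ), ρ_τ(u) = u(τ − 1{u<0}).
The assumption is linearity of each conditional quantile in age and
duration; the sensitivity analysis (below) relaxes it with splines.

**Solver.** The minimisation is posed as the standard linear program
(`min τ·1ᵀu⁺ + (1−τ)·1ᵀu⁻ s.t. Xβ + u⁺ − u⁻ = y, u± ≥ 0`) and solved
with HiGHS through `scipy.optimize.linprog` using sparse constraint
matrices. Two deterministic refinements follow:

* *interpolation polish*: a basic optimal solution interpolates `p`
  observations when the design is in general position, so the solution
  is snapped onto the exact interpolation of the `p` smallest-residual
  points whenever that does not increase the loss — this removes solver
  round-off and makes the fit agree with a brute-force enumeration
  oracle to 1e-9;
* *minimal-norm tie-break*: among loss-ties (tolerance 1e-8), a second
  LP selects the coefficient vector with the smallest L1 norm of the
  slopes, so degenerate cases (e.g. a constant outcome) have a unique,
  platform-independent answer.

**Classification.** Participant `i` is **low** if `yᵢ < q̂₂₅(xᵢ)`
(strictly), **high** if `yᵢ > q̂₇₅(xᵢ)` (strictly), otherwise **normal**;
quartile bins are 1: `y < q25`, 2: `q25 ≤ y < q50`, 3: `q50 ≤ y ≤ q75`,
4: `y > q75`, so bins partition the line and agree with the three
groups. Ties with a fitted quartile count as normal — consequential for
EQ-5D, where a sizeable mass sits exactly at 100; the strict reading is
this package's convention. Numeric ties are recognised with an absolute
tolerance of 1e-9 so that float round-off in the fitted surfaces cannot
flip a boundary case.

**Quantile crossing.** The three surfaces are fitted independently and
can cross in covariate regions with little data. Crossing at any
participant's covariates is detected, reported in a crossing table, and
repaired pointwise by sorting the three fitted values; the default
cohort produces no crossings.

**Discordance.** With bins `e` (EQ-5D) and `v` (VAS), a participant is
`lower_vas` iff (e=4 ∧ v∈{1,2}) ∨ (e∈{3,4} ∧ v=1), `higher_vas` by the
mirror-image rule, otherwise `within_expectation`. Of the 16 bin pairs,
exactly 3 are discordant in each direction.

## Multinomial association models

Group membership (low / normal / high, reference = normal; or the
discordance label, reference = within expectation) is modelled with
multinomial logistic regression. Fitting is delegated to statsmodels'
`MNLogit` and then polished with safeguarded Newton steps until the
score vector is below 1e-8 in the maximum norm; effects are reported as
relative risk ratios `exp(β)` with Wald 95% CIs (z = 1.96), a
presentation convention matched to epidemiological practice.

**Model building.** Sex, clinical phenotype and the SRDSS
gait-impairment class are always included. Candidates are then tried
one at a time, in a pre-specified order (symptoms, symptom count,
benefits/employment, sociodemographics and risk factors, DMT class,
first symptoms, comorbidities, BMI) and retained iff the AIC
(2k − 2·loglik) falls by **2 or more** points — a drop of exactly 2.0
retains. Forward selection is order-dependent; the order is a
configuration input with the documented default. MSSS and EDSS are never
candidates: MSSS is added only in a separate re-fit of the selected
model on the subsample with an observed MSSS, reported as a per-unit
RRR.

**Separation.** Sparse cells (e.g. severe gait impairment in the
high-HRQoL group) can separate; any coefficient beyond ±15 on the log
scale triggers a warning naming the covariate, a singular information
matrix falls back to a pseudo-inverse, and CIs degenerate to [0, ∞) as
they should.

**Collinearity.** Generalised variance-inflation factors per term
(categorical dummies aggregated) from correlation-matrix determinants;
terms with GVIF^(1/(2·df)) > √5 are flagged, and the design condition
number is reported.

## Sensitivity analysis: simultaneous quantile regression

The categorisation into three groups loses information, so the three
quartiles are also modelled jointly on the continuous scores:
restricted cubic splines (Harrell parameterisation; 3 knots at the
10th/50th/90th percentiles by default, so 2 basis columns per variable,
linear beyond the boundary knots) for age and duration, plus the
confounders and the candidates retained by the main analysis. Point
estimates per τ are the same pinball-loss minimisers as in the
segmentation module (shared solver); the joint covariance across all
three τ comes from B = 100 participant-level bootstrap resamples, each
refitting all τ on the same resample. P-values are two-sided normal
approximations with bootstrap SEs; the q25-vs-q75 contrast per
coefficient uses the joint covariance. A candidate is retained iff
p < 0.05 at *any* of the three τ — the looser of the defensible
readings, chosen because a variable acting on a single tail is exactly
what the method is meant to surface. Bootstrap resamples with a
rank-deficient design are redrawn (at most 10 times per replicate, with
the count logged); bootstrap refits use HiGHS's interior-point solver
and skip the tie-break polish for speed, which affects only the
covariance estimate, never the reported point estimates.

## Scoring

**EQ-5D index.** A value-set tariff maps a five-domain profile to a
utility `U = 1 − Σ decrements`; the index rescales `[U_min, 1]` linearly
to `[0, 100]`, so the tariff's worst profile scores 0 and full health
100. Published value sets are licensed and not redistributed here: the
tariff is a user-supplied CSV + JSON header, validated against its
declared invariants (level-1 decrements of zero, full health = 1,
`U_min` equal to the worst profile's utility). The packaged
`toy_value_set` is synthetic, for tests and examples only. Whether the
0–100 index used in registry practice is exactly this linear rescale is
a convention of this package; the tariff's declared level range (3L vs
5L) governs which profiles are valid.

**MSSS.** EDSS scores are rank-normalised within strata of equal
integer-year disease duration: MSSS = 10·midrank/(n+1) with average
ranks for ties, so values lie in the open interval (0, 10) and measure
disability relative to others with equal disease duration (progression
speed). Strata smaller than 5 are pooled with their nearest neighbours
symmetrically outward (d±1, d±2, …) until the minimum is met; pooled
neighbours contribute reference ranks only. The 10·midrank/(n+1)
normalisation is the documented convention here and is isolated behind
`MsssParams` so a published lookup-table mode could be added.

## Preprocessing

Inclusion requires a complete HRQoL assessment — both EQ-5D and VAS at
the same visit, the stricter reading of "complete" — plus non-missing
age and diagnosis information; exclusions are counted by reason. Per
participant the *last complete* measurement is kept (date ties broken by
file order, for determinism). Missing values of five categoricals
(phenotype, living situation, marital status, education, smoking) become
explicit unknown levels rather than dropped rows. Missing BMI is imputed
deterministically (no noise) by least squares on age, sex, SRDSS class
and diabetes/cardiovascular comorbidity; imputed values are flagged and
re-running is a no-op. Deterministic single imputation understates the
imputation variance, acceptable at the ~3% missingness the pipeline
assumes.

## The synthetic cohort generator

The generator emulates a national MS-registry cross-section of
n = 1697 participants. What it matches, by construction or calibration:

* **Demographics.** Age ~ truncated normal on [18, 90] with location
  47.8 / scale 15.3, solved so the quartiles are ≈ 38/49/58 years.
  Duration ~ gamma (shape 1.021, scale 20.5) truncated at age − 16
  (diagnosis at 16+); the *post-truncation* quartiles are calibrated to
  ≈ 4/9/17 years — the truncation is substantial for younger
  participants, so the untruncated gamma is deliberately heavier.
  Female share 73.1%; phenotype distribution 4.1% CIS / 10.6% PPMS /
  68.4% RRMS / 16.1% SPMS / 0.8% unclear.
* **Latent severity.** S = 0.035·duration + phenotype effect
  (PPMS 1.2, SPMS 1.5, CIS −0.8 relative to RRMS) + N(0,1),
  standardised with frozen population constants. Severity drives the 12
  symptom flags (logistic models whose intercepts are solved to hit the
  published prevalences given chosen slopes), the SRDSS class
  (thresholds at the 70.3/90.9 severity percentiles), EDSS (affine in
  the severity z-score, rounded to the half-point grid), disability
  benefits, employment and DMT class (softmax with severity gradients
  and intercepts calibrated to the published marginals).
* **HRQoL.** Latent E* = P + e and V* = 0.8·P + v, where P is the
  covariate predictor (SRDSS, benefits, the 12 symptoms, small age and
  duration trends) and (e, v) are standard bivariate normal with
  residual correlation 0.5415 — calibrated once, by grid search at
  large n, so the *total* Spearman correlation between the two observed
  scores is ≈ 0.74; shipped as a frozen constant because only the total
  correlation is an observable target. The observed scores are monotone
  rank-quantile maps of E* and V* onto piecewise-linear target quantile
  functions anchored at the published group quantiles; the EQ-5D map is
  censored above at 100 with a ceiling mass of 0.16 (chosen so the
  classified highest-quartile group has median exactly 100 with a
  comfortable margin), and VAS is rounded to the integer grid. Rank
  mapping makes the *marginals* essentially deterministic at any n while
  leaving *who* gets which score random, which is what the group-level
  calibration needs.
* **Missingness.** Five categoricals and BMI go missing completely at
  random at rates ≤ 3.3%; EDSS is observed with probability 0.5522
  (≈ 937/1697), emulating partial registry linkage.

What it does **not** emulate: joint covariate structure beyond the
single severity latent (published sources give only marginals, so any
richer dependence would be invention); longitudinal trajectories (one
measurement per participant); informative missingness; reporting
artefacts such as digit preference in VAS beyond integer rounding.
Passing calibration tests therefore demonstrates that the *pipeline*
behaves correctly on data with realistic marginal and dependence
structure — not that real registry effect estimates would be
reproduced. Real-data regression coefficients are deliberately out of
scope; estimator correctness is instead checked by closed-form cases
and parameter-recovery simulations with known ground truth.

## Numerical and design choices

* LP feasibility/optimality at HiGHS defaults; oracle agreement asserted
  to 1e-9 after the interpolation polish.
* Boundary ties in classification resolved to "normal" with a 1e-9
  absolute tolerance.
* The multinomial Newton polish stops at max|score| < 1e-8 or, under
  separation, at the last finite improvement.
* Bootstrap seeds derive from the run seed via `SeedSequence([seed, k])`
  with a distinct stream index `k` per stage (generation 0, missingness
  1, bootstrap 2), so stages are independently reproducible.
* Problem sizes in the test suite: calibration checks use the full
  n = 1697 cohort; recovery simulations use 100 replicates at n = 5000
  (multinomial CI coverage) and 12–50 replicates at n = 600–1200 for
  selection/power properties — large enough for the asserted rates,
  small enough to keep the suite quick.

## Known limitations

* Independently fitted quantiles can cross; the pointwise sort repair is
  standard but ad hoc. A crossing-constrained joint fit is out of scope.
* Wald CIs (not profile likelihood) are used throughout; with separated
  cells they are honest about their own breakdown (infinite endpoints)
  but remain approximations.
* Forward selection is order-dependent by nature; the trace makes every
  decision auditable, and the order is configurable.
* The generator's benefit/employment/DMT marginals are calibrated under
  the severity-gradient softmax and drift by < 1 percentage point from
  their targets; symptom prevalences are matched to ~1%.
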