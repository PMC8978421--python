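# Methods

## Scope and model

`rddframes` studies one question: what changes when a dual-frame (DF)
landline + cell RDD survey is replaced by the single-frame (SF) cell-only
design, holding everything else fixed. The SF design is built
counterfactually — the cell-frame respondents of the realized DF wave are
re-weighted as if the landline sample had never been drawn — so the two
samples are dependent by construction, exactly as in a real as-if analysis.
The comparison covers four layers: fieldwork productivity and AAPOR outcome
rates, design-weight dispersion, representativeness (standardized distances
and R-indicators), and calibrated prevalence estimates with design effects.

### Selection probabilities

The DF selection probability is the multiplicity estimator
`π_df = (n_LL/N_LL)(t_LL/e_LL) + (n_C/N_C)(t_C/e_C)`, interpreted as the
*expected number of completed interviews* of a person: each of their `t_LL`
landline numbers enters the sample with probability `n_LL/N_LL` and the Kish
stage picks them with probability `1/e_LL`; each of their `t_C` cell numbers
reaches them directly (`e_C = 1`). Under this interpretation the weighted
total `Σ 1/π` over completed interviews — duplicates retained — is exactly
unbiased for the size of the covered population, which is the property the
Monte-Carlo tests check. The simulator therefore keeps duplicate interviews
of the same person; at the default sampling fractions (≲10⁻⁴ per number)
duplicates are vanishingly rare. Probabilities are computed from
*reported* multiplicities (a configurable misreport switch perturbs them),
capped at 3 numbers per frame, the usual practice to limit weight extremes;
no weight trimming is applied. A computed `π > 1` raises instead of being
clamped, since it signals mis-specified frame counts.

### Raking

Calibration is plain raking ratio (IPF): cycle over the margin variables,
multiplying weights by target/current category totals. Defaults: sex×age is
raked as one joint 12-cell margin (two sexes × six age bands) with
education, household size, urbanization and region as marginal constraints;
a `marginal` specification that splits sex and age is available. Margins are
shares scaled to the reference population total, so calibrated weights sum
to the population size (needed for design-effect and total checks). Stopping
rule: maximum relative margin deviation < 1e-8 or 100 cycles — far below any
reporting precision; the fixed point is order-invariant to ~1e-6, which a
test verifies. Structural zeros (positive target, empty sample category)
abort with the offending category named; no bounded/logit raking is offered.

### Balance diagnostics

Standardized distances use the pooled-binomial denominator
`d = 100(p_B − p_A)/sqrt((p_A q_A + p_B q_B)/2)`; aggregation is a strictly
unweighted two-level mean of absolute values (|d| over a variable's
categories, then D over variables) — no category-size weighting, which is
what makes the published worked-example aggregates reproducible from their
printed category values. `d` is 0 by continuity when both shares are equal
(including both 0 or both 1) and undefined when they are degenerate and
unequal. Balance of the *calibration* covariates is diagnosed with design
weights (what calibration has to repair); balance of *external* covariates
with calibrated weights (what calibration leaves behind). Report tables
round half-up to one decimal — Python's banker's rounding would mis-round
ties like 10.25 — and an option aggregates from rounded category values to
match printed tables exactly.

### R-indicator

The R-indicator is `R = 1 − 2·S(ρ̂)` with `S` the population-weighted
standard deviation of predicted response propensities. Propensities come
from a main-effects logistic membership model on the sample stacked against
the benchmark population (sex, age band, education by default). Sample rows
enter with their design weights normalized to the achieved sample size `n`:
with the benchmark being the full population of size `N`, the fitted
membership odds `n·f_s(x)/(N·f_p(x))` then estimate the response propensity
ρ(x) directly (if the sample were drawn with propensity ρ(x), the sampled
density is f_s = ρ·f_p/ρ̄ with ρ̄ = n/N, so the odds equal ρ). The odds are
capped at 1 against estimation noise. On a saturated two-stratum design this
reduces to the closed-form two-point standard deviation, which is the
acceptance check. Partial (variable-level) R-indicators and standard errors
are out of scope.

### Estimation

Prevalences are Hájek ratio means; variances use Taylor linearization under
a with-replacement single-stage approximation with calibrated weights
treated as fixed, `var(ȳ) = Σ w²(y−ȳ)²/(Σw)²`. This is the standard
conservative default when the weighting pipeline is heterogeneous; a
bootstrap oracle in the tests bounds its discrepancy at ~10% on a fixed
sample. Whether calibration residuals should enter the variance is a known
refinement deliberately not implemented; SEs are therefore approximate for
the calibrated estimators. `deft = sqrt(var(ȳ)/(p(1−p)/n))` with
`s² = p(1−p)` for binary indicators, so equal-weight simple random samples
give deft = 1 identically. Subgroup tables (exact ages 18–30 and 60–75)
reuse the full-sample calibrated weights without re-calibration. AAPOR RR3
uses `e` = known-eligible / (known-eligible + known-ineligible) among
resolved numbers, per frame (the CASRO proportional-allocation convention).

## Synthetic population: what it emulates, what it does not

The generator draws a finite population of 18–75-year-olds with:

* **Demographics** from French-like margins (sex 48.7/51.3; six age bands;
  six education levels; five household sizes; six urbanization levels;
  twelve regions). Sex×age is drawn jointly as the product of the margins;
  education, urbanization and region are independent person-level draws.
* **Households** formed by grouping persons of each household-size class
  after sorting on jittered age, inducing intra-household age correlation
  (couples/flatmates are age-alike) so the Kish eligible count `e_LL` varies
  realistically. All generated persons are eligible, so `e_LL` equals the
  household size; the "≥5" class is materialized at size 5. Remainders of a
  size class form one smaller household.
* **Telephone equipment**: cell ownership is person-level,
  logistic-in-(age, education) around age-band baselines falling from 99.5%
  (18–24) to 87% (65–75), implying ≈95–96% overall; landline ownership is
  household-level (decided from the household head's age/education), rising
  from 58% to 93% across age bands, ≈77% overall. Number multiplicity per
  owned frame is 1/2/3 with probabilities 0.90/0.09/0.01 — the published
  sources give no multiplicity distribution, and the weight formulas only
  need `t ≥ 1` variation to be exercised. The exact model-implied marginal
  rates are computable (`implied_equipment_rate`) and checked against
  realized rates.
* **Frames** padded with non-working numbers to 50% (landline) and 33%
  (cell) non-working shares, the rates such surveys report.
* **Health indicators** (the Minimum European Health Module trio, obesity,
  physical inactivity, daily smoking, lifetime suicidal attempt) with
  baselines near the published whole-population estimates and logistic age /
  education gradients in the directions known from social epidemiology.
  Daily smoking and suicidal attempts additionally carry a residual
  phone-class effect (cell-only +0.18/+0.15 log-odds, landline-only
  −0.25/−0.15): phone equipment is associated with these behaviours beyond
  demographics, which is precisely what makes the SF design's coverage bias
  non-removable by calibration — the mechanism the package exists to expose.
* **Response behaviour**: per-call answer probabilities by frame × age band
  (landline answering rises with age, cell slightly falls) and cooperation
  rising with age, yielding overall RR3 in the 40–50% range typical of
  French telephone surveys. Contact is a truncated-geometric process
  (default cap 12 calls); on the landline route the answerer is a uniform
  household member and a handoff (one extra attempt, success 0.85) is needed
  when the Kish selectee is not the answerer. Partial interviews (2% of
  cooperators) exercise RR3's P term; 1% "other" outcomes its O term.
  Identified non-working numbers (80%) are coded NE; never-answered numbers
  stay unknown-eligibility (UH/UO).

Not emulated: calendar/time-slot call scheduling, interviewer effects,
measurement/mode effects (responses equal latent values), smartphone/SMS
modalities, geography beyond categorical labels, institutional population,
and within-household correlation of anything but age. Response propensities
depend only on frame and age — nonresponse is ignorable given the
calibration variables — so passing recovery tests show the estimators work
under the design they assume, not that calibration would repair a real
survey's non-ignorable nonresponse.

## Default study conditions and problem sizes

The default scenario is a population of 50,000 with a dialing budget of
4,000 landline + 6,000 cell numbers (the 40/60 split such dual-frame waves
use), giving roughly 3,000 DF completes of which ~2,100 are cell. The
direction checks (SF deft < DF deft per indicator, CV_SF < CV_DF) refer to
this scenario with fixed seeds. Unit and property tests run on scaled-down
populations (2,000–20,000 persons) chosen so the whole suite completes in
well under a minute; Monte-Carlo properties use 60–200 fieldwork replicates
on a fixed 4,000-person population, with 4-standard-error acceptance bands.
Seeds are managed by `SeedSequence` spawning so each stage has an
independent stream and replicates are independent.

## Known limitations

* SEs ignore the calibration step (fixed-weight linearization) and the
  dual-frame overlap's covariance structure.
* The R-indicator's benchmark is the synthetic population itself; with a
  real census benchmark the membership model would inherit the census
  weights, a path the API supports (`benchmark_weights`) but the pipeline
  does not exercise.
* Counterfactual SF estimates share realized fieldwork with the DF sample,
  so DF–SF differences cannot be tested as independent samples — inherent to
  the as-if design, not a defect.
* Household formation matches the person-level household-size margin, not a
  household-level size distribution; both cannot hold simultaneously with
  all persons eligible.
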