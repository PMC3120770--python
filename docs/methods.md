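# Methods

## Model structure and conventions

The core is an annual-cycle Markov cohort model with states S (alive with
schizophrenia), R (recovered, no disability weight, no treatment costs) and
D (dead, absorbing). A prevalent cohort (default 370,000 persons, a
placeholder on the order of Thai schizophrenia prevalence) enters at a
single start age of 30 and is followed to age 80. The real patient
population has an age distribution; a configurable start age stands in for
it because no published age structure is available.

Numerical conventions, chosen to mirror spreadsheet-style decision models:

* State membership is counted at cycle start; the discount factor is
  `(1+r)^{-t}` with `t = 0` in the first cycle. No half-cycle correction is
  applied.
* Competing exits from S (remission, suicide, weight-attributable death,
  other-cause death) combine *additively*. The probabilities involved are
  small (≤ a few percent each), where the additive and rate-based
  conversions agree to second order; if a parameter draw makes the exits
  sum above 1 the model raises rather than silently renormalizing.
* YLD: `Σ_t disc(t) · S_t · DW`. Deaths during cycle `t` lose the
  discounted years a survivor would still have accrued inside the horizon,
  `u = t+1 … T−1`. This endpoint keeps YLD and YLL mutually consistent
  (a death exactly cancels the dead person's would-be YLD stream plus
  residual life years); the alternative endpoint `T` would count one year
  survivors never accrue. YLL therefore uses the age-80 horizon, not
  life-table expectancy.
* Deaths are attributed to causes (suicide, weight, other) in proportion to
  the cause-specific exit probabilities in the cycle they occur; recovered
  patients can only die of other causes.

DALYs averted versus the null decompose into severity (YLD difference plus
the second-order other-cause-survival interaction, so the three components
sum exactly to the total), weight gain (negative when the drug adds
mortality), and suicide.

## Effects pipeline

Trial-arm summaries → Hedges' g with the small-sample correction
`J = 1 − 3/(4·df − 1)` → DerSimonian–Laird random-effects pooling (moment
estimator of τ², truncated at zero) → disability-weight change
`ΔDW = g · SD_survey · slope`, where the slope is that of the linear map of
BPRS-E scores (24–134) onto the Dutch schizophrenia disability weights
(0.21–0.98). The linearity of the score→weight map is an assumption; a
rank-based mapping would be an alternative but the linear form is the one
the defaults encode.

Side effects and adherence:

* EPS: proportions affected are 25% on typicals and 13% on atypicals (all
  atypicals assumed equal), with disability weights 0.422 (moderate) and
  0.453 (severe). The moderate/severe split among those affected is not
  published; `severe_share` defaults to 0.5, making the atypical-vs-typical
  adjustment (0.13 − 0.25) × 0.4375 = −0.0525 DW.
* Adherence (default 47%, SD 7.4%) scales DW changes and weight gain
  linearly and moves the suicide RR toward 1 as `1 + a·(RR − 1)`. Costs are
  *not* scaled: non-adherent patients still attend and receive
  prescriptions. This is a deliberate, configurable asymmetry.
* Weight gain converts to a BMI shift with a default reference height of
  1.6 m. Mortality risk is log-linear in BMI (β = 0.05 per unit, a
  synthetic placeholder of plausible magnitude); the added annual death
  probability is `p_base · (exp(β·shift) − 1)`, i.e. minus the potential
  impact fraction applied to a baseline weight-related mortality of
  0.003/yr. The general PIF routine integrates any RR function over a
  normal exposure distribution by adaptive quadrature and is validated
  against the closed form `1 − exp(β·δ)` that holds exactly for log-linear
  RR.
* Clozapine's suicide RR defaults to 0.53 (the text value; 0.54 appears in
  one published table) and is configurable.

## The 'do nothing' comparator

The null runs the same cohort with zero treatment effect, the null
disability weight taken from the survey severity distribution (mean mapped
DW ≈ 0.30), hospitalization at double the treated-typicals rate (0.54 vs
0.27, reflecting that typicals halve hospitalization) and hospitalization
as its only cost. The suicide rate in the null equals the base rate used
for every RR = 1 strategy — drugs without a suicide-specific effect neither
add nor avert suicide deaths, which is why only clozapine shows a suicide
component.

For severity-restricted strategies (clozapine for BPRS > 40) the cohort is
split at the cutoff using the survey sample; each stratum gets its own null
DW (the mean mapped DW of its scores) and the eligible fraction is always
derived from the survey, never asserted.

## Costs

Annual per-person costs accrue in state S only: drug + administration,
side-effect treatment/monitoring (benzhexol; blood tests for clozapine),
hospitalization (`rate × unit cost`), and patient/family time and travel.
The hospital unit cost (30,000 baht/admission-year) is a synthetic
placeholder chosen so the published component table is internally
consistent: 0.27 × 30,000 = 8,100 baht for typicals, and the atypical and
FI hospitalization components (5,200 and 4,500 baht) then imply rates of
0.173 and 0.15.

Family intervention adds an amortized startup cost and the 10-session
program (provider side 2,000 baht; participant time 3,100 baht) in the
first year, and booster-session costs (360 + 600 baht) from the second
year onward. This reproduces the published pattern of FI+risperidone being
~4,000 baht more expensive than risperidone alone in the first year and
only marginally more expensive later.

Risperidone's drug cost is decomposed as administration plus
`tablets/day × 365 × tablet price` (one 2 mg tablet at the expected 4-baht
generic price), which is what the price sweep and the bisection threshold
finder (tolerance 0.01 baht) vary.

## Economics and uncertainty

The frontier sorts strategies (plus the implicit (0,0) null) by net cost,
removes strictly dominated points, then iteratively removes
extended-dominated points until ICERs strictly increase. Ties break
deterministically: equal cost and effect keep the lexicographically first
name; equal cost keeps the higher effect. A cost-saving, more effective
anchor step is labelled "dominant" and carries no ICER. Report rounding is
half-up to 2 significant figures — half-up, not banker's, because published
decision-model tables round 625,000 to 630,000.

PSA draws every parameter with a distribution entry independently (beta for
probabilities and fractions, gamma for costs, normal for DW changes,
lognormal for the suicide RR), re-derives the administration/tablet
decomposition after cost draws, rejects and redraws invariant-violating
parameter sets (bounded retries), and reruns the full pipeline per draw.
Acceptability uses net monetary benefit (`λ·ΔE − ΔC > 0`), per strategy
versus the null and incrementally along the deterministic frontier steps;
95% intervals are 2.5/97.5 Monte Carlo percentiles. Default 2,000 draws;
all randomness flows from one `numpy` Generator seed, so runs are exactly
reproducible.

## Synthetic data: what it emulates and what it does not

* **Trials** (`gen_trials`): study-level true effects are
  normal(true_g, τ²); arm means are set so the standardized difference
  equals the study effect at the generated arm SD. Within-study sampling
  noise enters through the variance formula rather than by perturbing the
  means, which makes the DL coverage calibration (k = 20, g = −0.5,
  τ² = 0.02, 200 replicates, ≥ 90% CI coverage) conservative.
* **Survey** (`gen_bprs_survey`): 307 truncated-normal BPRS-E scores
  (mean 34.2, SD 10 on [24, 134]) whose expected fraction above the
  clozapine cutoff of 40 is one third. Real severity distributions are
  right-skewed mixtures of in- and outpatients; only the cutoff fraction
  and the spread that drives the effect-size translation are emulated.
* **Parameter set** (`gen_parameter_set`): embeds the published point
  values (DW changes and CIs, weight gains, adherence, EPS inputs,
  first-year cost components, hospitalization rates, discounting,
  thresholds) and synthetic placeholders — flagged `provenance:
  "synthetic"` — for transition probabilities (remission 0.02/yr, suicide
  base 0.005/yr, banded other-cause mortality rising from 0.002 to
  0.035/yr), the hospital unit cost, and distribution spreads.

Passing tests on these inputs demonstrate the *mechanics* — aggregation
paths, dominance logic, calibration, determinism — and that the published
table components and price-threshold behaviour are reproduced; they do not
validate the unpublished transition probabilities, so absolute
population-level DALY and cost totals from the default run are
order-of-magnitude, not replications.

## Problem sizes

Default runs use 50 annual cycles per strategy arm, a 307-person survey,
200 meta-analysis replicates for calibration, 1,000 random instances for
the frontier oracle comparison, 10,000 persons for the microsimulation
cross-check, and 500–2,000 PSA draws; the whole test suite and the
acceptance script each complete in seconds on one CPU.

## Known limitations

* Single start age; no Thai life-table or age/sex demography.
* No costs of treating weight-gain-related disease; no CPI machinery
  (inputs are 2005 baht).
* Independent PSA draws — no correlation between, e.g., cost components.
* Patients stay on their assigned treatment for life; no switching.
* The full generalized back-calculation of the 'do nothing' scenario is
  simplified to the parameterization described above.
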