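# Methods

This note records the scientific conventions, modelling assumptions and
numerical choices behind `ckdcdss`, in the spirit of a statistical
methods appendix. Nothing here states a result the test suite or
`scripts/acceptance.py` does not itself compute.

## Renal calculators

**Creatinine eGFR** uses the CKD-EPI 2009 piecewise power law
(κ = 0.7/0.9 and α = −0.329/−0.411 for female/male, slope −1.209 above
the knot, age factor 0.993^age, female factor 1.018). The historical
Black-race coefficient (1.159) sits behind an explicit flag, default
off: contemporary practice omits it, and which convention a given lab
used at any epoch is a local fact the data model cannot recover. The
function is continuous at the sex-specific knot and strictly decreasing
in creatinine and in age; both properties are asserted by tests.

**Cystatin-C eGFR** uses the CKD-EPI 2012 cystatin-alone equation
(knot at 0.8 mg/L, exponents −0.499/−1.328, age factor 0.996^age,
female factor 0.932).

**Kidney failure risk** is the 4-variable KFRE (age, sex, eGFR, ACR) at
the 5-year horizon with the North-American calibration: risk =
1 − 0.9365^exp(lp), with the linear predictor centred at the derivation
cohort means (−0.2201·(age/10 − 7.036) + 0.2467·(male − 0.5642)
− 0.5567·(eGFR/5 − 7.222) + 0.4510·(ln ACR − 5.137)). The 4-variable
variant is the minimal set computable from the triple-marker workflow.
When the rules engine needs a KFRE and none is supplied, it evaluates
the equation on the cystatin-based eGFR, the more reliable filtration
marker in this workflow; callers may pass a precomputed value instead.

eGFR values are never rounded before threshold comparisons; all
thresholds compare full-precision values, so the inequality dialect is
independent of display formatting.

## Rules engine

Risk stratification and the referral criteria use strict inequalities
exactly as the clinical logic states them: high risk iff eGFR_Cys < 60
or ACR > 30; referral iff any of eGFR_Cys < 30, K > 5.5 mEq/L,
ACR > 300, SBP > 150 mmHg despite ≥ 3 antihypertensive classes
including a diuretic, or 5-year KFRE > 3%. Values exactly on a boundary
(eGFR_Cys = 60 with ACR = 30; K = 5.5) satisfy neither strict clause
and resolve to the less aggressive branch; every comparator lives in a
single `RuleThresholds` object so the dialect is visible, overridable
and testable.

Potassium management is the one under-specified domain: the source
logic names "diet and diuretic recommendations" without cutoffs. The
defaults are clinically conventional tiers — K in (5.0, 5.5] triggers
diet counseling; K > 5.5 triggers both diet counseling and diuretic
adjustment (and independently fires the referral criterion). Both
cutoffs are configurable.

Missing inputs are handled as *unassessed*, never imputed: a patient
without a potassium result cannot satisfy the potassium criterion, and
the provenance map records why. A "confirmed" low cystatin eGFR is
operationalized as the single panel value, because the workflow
measures cystatin once per patient.

Correctness is established two ways: handwritten examples at the
printed thresholds, and a brute-force table-driven re-statement of the
bullet-list rules that must agree with the engine on 10,000 randomized
patient states (plus monotonicity: worsening the panel never removes an
action or criterion).

## Cohort selection

Calendar arithmetic is fixed to a bit-stable dialect: day granularity,
half-open windows [start, index), "12 months" = 365 days, "18 months" =
548 days, the eGFR band 30–59 inclusive on both ends, and "at least 90
days apart" as a date difference ≥ 90. Eligibility eGFR is always
recomputed from stored outpatient creatinine results (age taken at the
collection date) rather than trusting a stored eGFR column — one
source of truth. When several qualifying pairs exist, the evidence pair
is the one with the most recent later date, ties broken by the earlier
first date, so reported evidence is deterministic.

Manual exclusions (pregnancy, limited life expectancy, cognition,
NYHA III/IV, EF < 25%, PCP discretion) are consumed as an input flag
table, not inferred: these judgements are unreliably captured in
structured EHR data. The funnel summary attributes each removed patient
to the first stage that removed them (inclusion → automated → manual →
opt-out) while the per-patient decision retains every triggered code,
so funnel conservation (initially eligible = included + every bucket)
holds by construction and is asserted on every generated dataset.

## Cluster randomization

"Blocked on panel size" is realized as: sort providers by eligible-panel
size descending (ties by provider id), cut into consecutive blocks of
three, permute arm labels within each block. Any such scheme balances
provider counts exactly (±1) and patient counts approximately; the test
suite verifies that across 1,000 seeds the worst pairwise patient-count
gap is stochastically smaller than under simple randomization. The true
block structure used in any given trial is a statistician's unpublished
choice; this is one admissible implementation, and the sort order makes
assignments invariant to input row order.

## Trigger state machine and trial simulation

The alert displays iff: the encounter is a PCP visit with the patient's
own panel provider, the triple-marker panel is complete by the visit
date, the orders are not yet signed, and fewer than three displays have
occurred ("up to 2 additional visits" beyond the first = 3 display
opportunities, a configurable constant). Hovering is not opening;
"opened" is the accept click, which is what an EHR can count. Signing
is absorbing. The pharmacist task exists only in the eCDSS+ arm after
signing, due exactly 14 days later.

The trial simulator's behavior model is deliberately parameterized at
the *per-patient eventual* level — probability of ever completing labs,
of ever having a post-results PCP visit, of the PCP ever opening, of
signing once opened — because those are the quantities the
implementation funnel reports and the level at which observed rates are
available. Visit-level re-display mechanics are still exercised
(never-openers and openers-who-don't-sign accumulate the full three
displays); what is *not* modeled is a per-display opening probability,
which would compound across re-displays and change the funnel
interpretation of the parameters. Recommendations are recomputed at
each display from current tables and snapshotted into the event
payload.

The simulator materializes each patient's triple-marker results from
latent physiology stored in the generator's ground-truth sidecar; the
decision engine and cohort selector only ever see materialized tables.

## Safety surveillance

Weekly review comparators are exactly as specified: decline
(baseline − current)/baseline **> 0.30** (strict), ACR **≥ 1000** mg/g
(inclusive), discordance |eGFR_Cr − eGFR_Cys| / eGFR_Cr **> 0.30**
(strict). The discordance denominator is the creatinine-based value
(the routinely reported one) by default and configurable, since the
ratio's base is an operational convention. Baseline eGFR_Cr is the most
recent pre-enrollment outpatient value. Referral non-adherence fires
when a signed nephrology referral is older than a configurable lag
(default 90 days) with no subsequent nephrology visit. Flags are keyed
by (patient, rule, ISO review week), making re-runs idempotent.

## Trial metrics

Funnel proportions carry explicit numerator/denominator pairs; zero
denominators produce explicit n/a values. "Sustained BP control" means
a run of ≥ 2 *consecutive BP-measured* visits all below 140/90 (both
strict); visits without a BP measurement are invisible to the run,
because calendar adjacency is not well-defined for irregular visit
schedules. The endpoint BP is the last in-period measurement carried
forward (LOCF); if nothing was measured in-period the baseline carries
forward. Albuminuria for the ACEi/ARB process outcome is ACR > 30 mg/g
on the most recent result, consistent with the stratification
threshold.

## Power analysis

The analytic minimal detectable difference is
δ = (t₁₋α/₂,df + t_power,df) · σ · √(2·DE/(k·m)) with DE = 1 + (m−1)ρ
and df = 2(k−1). The t-quantile convention matters: with k = 23,
m = 15, ρ = 0.025, σ = 5 and α = 0.05 it gives δ = 1.2674 (printed
1.27), whereas normal quantiles give 1.24; both modes are exposed and
the small-sample t convention is the default because it matches the
behavior of the standard cluster-sample-size routines. The simulation
route tests arm differences with a pooled two-sample t-test on cluster
means — exactly valid under the balanced Gaussian random-effects model,
so simulated power at the analytic δ should (and does, within 3
Monte-Carlo standard errors at 5,000 replicates) hit the target, and
the rejection rate at δ = 0 calibrates to α.

## Synthetic data generator

The generator emulates a single academic general-internal-medicine
practice at a fixed index date: 81 providers by default, allocated to
roles by largest remainder over a 47:31:3
attending/resident/nurse-practitioner mix; Poisson panel sizes (mean
12); patient demographics, comorbidity, medication and language mixes
drawn at the prevalences observed in such a CKD-eligible population
(age ≈ 70 ± 9 truncated to 18–80 for the eligible stratum, 45% female,
90/7/3% English/Chinese/Spanish, hypertension 72%, diabetes 38%, statin
67%, ACEi/ARB 61%, CKD on problem list 12%). A configurable fraction of
patients (default 0.65) carries an engineered qualifying eGFR pair
(targets drawn in 30–59, creatinine back-computed by exact inversion of
the CKD-EPI equation at the age on the collection date); every other
patient violates exactly one criterion, cycling deterministically
through thirteen violation kinds so any moderate dataset covers every
exclusion path. Systolic BP follows the two-component cluster model of
the power calculation — grand mean 128 mmHg, provider effect variance
ρσ², patient residual variance (1−ρ)σ², defaults ρ = 0.025 and σ = 5 —
with optional visit-level jitter (default 0, keeping the ICC exactly
interpretable and recoverable by one-way ANOVA). Visit-frequency
distributions are not reported for such practices; the default of ~3
ambulatory PCP visits per 18 months is an assumption and configurable.

What the generator does **not** emulate: real assay noise beyond an
optional lognormal jitter, correlated comorbidity structure, panel
switching mid-trial, informative visit timing, or free-text data.
Passing end-to-end tests therefore demonstrates the correctness of the
decision and trial logic under the stated model, not calibration of the
generator against any real population.

Problem sizes in the test and acceptance runs (hundreds of patients,
200 clusters × 15 for ICC recovery, 5,000 power replicates, 10,000
randomized rule states) were chosen to put Monte-Carlo error well below
the assertion tolerances while keeping the full suite fast enough for
routine development.

## Known limitations

- The KFRE calibration is the North-American 4-variable variant only;
  regional recalibration factors and the 8-variable equation are out of
  scope.
- The behavior model treats funnel stages as independent Bernoulli
  gates; real adherence is correlated with patient and provider
  characteristics.
- Outcome *analysis* models (GEE with exchangeable correlation, as a
  trial would pre-specify) are intentionally out of scope; the package
  computes the outcomes themselves.
- Safety review reconstructs referrals from signed recommendation
  snapshots; referrals placed outside the decision-support pathway are
  invisible to the non-adherence rule.
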