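# Methods

`rrms_cea` implements a retrospective-cohort cost-effectiveness analysis of
three disease-modifying-therapy (DMT) classes for relapsing-remitting
multiple sclerosis (RRMS): orally administered agents (dimethyl fumarate,
teriflunomide, fingolimod; `ORAL`), interferon beta-1a (`IFN`) and monoclonal
antibodies (natalizumab, rituximab; `MAB`). This note describes the models,
the generative stand-ins for the unavailable patient-level data, the
numerical choices, and what the tests do and do not establish.

## Data model and outcome definition

One row per patient: sex, integer age in years (≥ 16), therapy class and
agent, therapy-duration band (1–2, 2–3 or 3–4 years), three binary clinical
flags over the observation year — clinical relapse, disability progression,
new MRI lesion — and an annual direct medical cost in USD. The *composite
outcome* is the logical OR of the three flags and is always re-derived from
them, never read from a file; *effectiveness* of a patient is its absence.
Cost aggregation is a linear tariff: annual drug-acquisition cost plus
Σ(count × unit cost) over lab tests, imaging and clinic visits, with unit
costs supplied by a flat YAML configuration (no discounting and no currency
conversion on the one-year horizon).

Two modelling codings are fixed once and recorded in run metadata: age
enters regressions as continuous years; sex as female = 1; therapy duration
as the band midpoint (1.5 / 2.5 / 3.5 years). Reporting age bands
(16–25, 26–35, 36–45, > 45) are derived, closed on the left, and used only
for frequency tables.

Inclusion screening applies six rules in fixed priority order — RRMS
diagnosis, diagnosis on/after the EMR cut-over (2015-05-01), age ≥ 18,
≥ 12 months observed, no other chronic conditions, no missing data — and
logs each exclusion with the first failing rule. Screening is idempotent.

## The deterministic cohort fixture

The underlying patient-level records are not publicly deposited, so
`make_study_fixture()` reconstructs a 146-patient cohort that reproduces the
study's published *marginal* structure exactly:

- arm sizes 40 / 66 / 40 with the published agent breakdown;
- sex 95 F / 51 M; age bands 42 / 62 / 27 / 15; duration bands 77 / 31 / 38;
- composite-free ("effective") counts 19/40, 26/66 and 33/40 per arm
  (inverting the published effectiveness rates 47.50%, 39.39%, 82.50%),
  summing to 68 composite events (46.58%);
- component totals 52 MRI lesions (35.62%), 23 progressions (15.75%) and
  31 relapses. The relapse total is only reported as "about 21%"; 31/146
  (21.23%) is adopted because every other printed rate is consistent with an
  exact integer count at two decimals;
- constant per-arm annual costs equal to the published means
  (11,044.66 / 15,381.31 / 16,762.54 USD), so the fixture's arm-mean cost
  differences are exact and its within-arm cost SDs are zero. The published
  cost SDs are parameters of the stochastic simulator instead.

Covariates are allocated within each arm by a deterministic largest-remainder
interleaving, *independent of outcome*; component flags are distributed over
the composite patients by cycling the arms (MRI flags fill first, then
relapse, then progression, wrapping so every composite patient carries at
least one flag and no composite-free patient carries any). The two
40-patient arms are given identical covariate compositions, which makes the
oral-vs-MAB propensity model exactly null (all scores 0.5) and their
matching complete — the matched increments then equal the raw arm-mean
differences by construction.

What the fixture deliberately does **not** reproduce: the joint
covariate–outcome distribution, hence the published adjusted odds ratios
(one-vs-rest ORs such as 3.409 for interferon), the per-class component bar
chart, and the bootstrap dominance percentages (96.05 / 99.59 / 99.9%). All
of these depend on patient-level joint structure that the printed margins do
not determine. Tests exercising those quantities therefore use the
stochastic simulator with planted ground truth, not the fixture.

## The stochastic simulator

`simulate_cohort(SimulationParams)` draws arms of fixed size with per-arm
Bernoulli composite events, component flags drawn from per-class conditional
splits (with at least one component forced when the composite fires, a
negligible bias at the default splits), lognormal annual costs matched to a
requested mean/SD (constant when the SD is 0), and covariates from the
published margins: P(female) = 95/146, age normal (31.3, 8.5) truncated to
[16, 70] and rounded to integer years, duration bands at 77/31/38
proportions. Defaults are the study conditions (arm sizes 40/66/40, event
probabilities 21/40, 40/66, 7/40, published cost moments). Covariates are
independent of outcome and of arm, so planted marginal odds ratios equal
conditional ones (no non-collapsibility gap), which is what the recovery
tests rely on. Everything is reproducible from a single integer seed.

Features of real cohorts the simulator does not emulate: confounding by
indication (covariates shifting both arm assignment and outcome), correlated
component flags beyond the shared composite, and heavy-tailed or zero-inflated
cost distributions. Passing recovery tests therefore demonstrate correctness
of the estimation machinery under the stated generative model, not robustness
to those phenomena.

## Logistic regression and odds ratios

`fit_logistic` maximises the Bernoulli log-likelihood by iteratively
reweighted least squares (Newton–Raphson) with step-halving, so the
log-likelihood is nondecreasing across iterations; convergence is declared
when the maximum absolute score falls below 1e-8 (at most 100 iterations).
The covariance is the inverse observed information at the optimum, and Wald
inference follows: OR = exp(β), CI = exp(β ± z·se), two-sided normal
p-value. Perfect or quasi-perfect separation is detected by monitoring
|β_j|·sd(x_j) (threshold 15 on that standardised scale) and raised as an
explicit error naming the culprit column — no silent penalisation, because
the analysis being reproduced reports plain maximum-likelihood ORs.

The class analyses fit **one model per class per outcome**: the outcome on
an indicator of that class versus the other two pooled, adjusted for age,
sex and duration midpoint — twelve models over the four outcomes (relapse,
progression, MRI lesion, composite). One-vs-rest is the only design that
yields an odds ratio for *each* of three classes, matching the "class
versus its counterparts on the other therapies" framing.

`min_sample_size` uses the two-group log-odds normal approximation: with
exposure prevalence q, baseline rate p0 and the exposed rate implied by the
target OR, n solves |log OR| / √(V/n) = z_{1−α/2} + z_{power} with
V = 1/(q·p1·(1−p1)) + 1/((1−q)·p0·(1−p0)). The nuisance rates are explicit
required inputs; the a-priori design summary this mirrors did not state
them, so no particular published n is asserted.

## Propensity-score matching

The propensity model regresses the treatment indicator on age, sex and
duration midpoint within the two arms being compared; constant covariate
columns are dropped (degrading gracefully to intercept-only, where every
score is the treated fraction). Matching is 1:1 greedy nearest-neighbour
without replacement on the **logit** of the score: treated units are visited
in descending score order, each takes its nearest unmatched comparator
within the caliper, and all ties break deterministically by smaller patient
id. The caliper defaults to 0.2 × the pooled n−1 SD of the logit scores (a
widely used convention); `caliper_sd=None` disables it. Zero pairs is an
error. The matching method itself was an open design choice — the analysis
being reproduced says only "propensity score matching" — so all three knobs
(scale, order, caliper) are explicit parameters with documented defaults.

## Bootstrap CEA

For a comparison (treat, comparator): ΔC is the matched-treated mean annual
cost minus the matched-comparator mean; ΔE the difference in the proportion
effective; ICER = ΔC/ΔE (undefined at ΔE = 0, with the quadrant still
assigned). Quadrants use the convention ΔE ≥ 0 → "more effective",
ΔC ≤ 0 → "cost-saving" (the boundary has measure zero for continuous costs
and matters only in degenerate tests); SE is dominance.

The default bootstrap (B = 10,000) resamples patients with replacement
*within each arm* (arm sizes preserved), then **re-estimates the propensity
model and re-matches on every replicate**, so matching uncertainty is
propagated; a cheaper `pairs` mode (match once, resample matched pairs) is
available behind a flag. Confidence intervals are percentile 2.5/97.5 — the
minimal-assumption reading of a bootstrap CI. Replicate r draws from a
substream keyed by (seed, r), so results are independent of execution order
and byte-identical under the same seed. Replicates where the propensity fit
or matching fails are redrawn from the same substream and counted; more than
10% failures aborts the run. The point estimate always comes from the
original, un-resampled matched data.

### Validating the quadrant probabilities

The dominance fractions cannot be checked against any published number (they
depend on the unavailable joint data), so they are validated against a
closed-form oracle on generative cohorts: with within-arm cost SDs small and
covariates independent of outcome, the bootstrap cloud for ΔE is
approximately normal around the *realised* cohort's estimate with variance
p_t(1−p_t)/m + p_c(1−p_c)/m for m matched pairs. At the study's arm sizes
(40/66) the cohort-to-cohort sampling noise dominates a single bootstrap
fraction, so the test averages the SE-quadrant fraction over 30 independent
cohorts; the cohort-averaged fraction has the closed form
P(N(μ_E, 2σ_E²) > 0) · P(N(μ_C, 2σ_C²) < 0) (sampling plus bootstrap
variance), and agreement is required within three empirical standard errors
of the 30-cohort mean. B = 300 per cohort keeps the within-run Monte-Carlo
noise well below that tolerance.

## Numerical and reporting conventions

- Percentages print at two decimals, rounded half-up (away from zero), to
  match tabular conventions; internal arithmetic is double precision and
  unrounded — notably, ICERs are ratios of *unrounded* increments.
- Sample SDs use the n−1 denominator; for a k-of-n binary indicator the
  reported percent SD equals 100·√(k(n−k)/(n(n−1))).
- Propensity scores are clipped to [1e-12, 1−1e-12] before the logit.
- All pipeline randomness derives from a single run seed; each CEA stage
  hashes (seed, stage name) to a 31-bit substream seed.

## Problem sizes in the test suite

The suite favours small, targeted simulations: IRLS-vs-direct-maximisation
on 30×3 problems; odds-ratio recovery on one 5,000-patient cohort; Wald
coverage over 1,000 null fits at n = 500; the quadrant oracle over 30
cohorts × 300 replicates; matching enumeration on ≤ 8-patient instances.
These sizes give oracle tolerances that are tight relative to the effects
being checked while keeping the full suite to a few tens of seconds.

## Known limitations

- The fixture guarantees margins only; any analysis sensitive to the joint
  covariate–outcome law (adjusted ORs, dominance fractions) is meaningful on
  simulated cohorts, not on the fixture.
- Separation is an error, not a model: arms perfectly predicted by the three
  covariates cannot be matched or adjusted for with this toolkit.
- The bootstrap treats patients as exchangeable within arm; there is no
  clustering (single-centre data) and no covariate adjustment beyond the
  three matching variables.
- No QALY/EDSS modelling, acceptability curves or net-monetary-benefit
  analysis: the effectiveness measure is the composite-free proportion over
  a single year.
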