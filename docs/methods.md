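# Methods

## Design

The package implements a case/non-case study inside a spontaneous-reporting
(ICSR) database. The design conditions on the reported event: reports carrying
the preferred term of interest (here "polymyalgia rheumatica", matched
case-insensitively with internal whitespace collapsed) are cases, all other
reports are candidate non-cases, and the exposure contrast is the reporting
odds ratio (ROR). Because reporting rates drift with time and the event is
age- and sex-patterned, each case is matched to five non-cases on exact age in
integer years, sex, and calendar year of reporting. Reports carrying the
"aggravated" variant of the event term are removed from both series: they
indicate prevalent disease and would contaminate either group.

Eligibility requires recorded age and sex. The same requirement is applied to
non-cases, although only strictly needed for the matching variables to be
defined; the alternative (allowing incomplete non-cases and dropping them at
match time) is equivalent here because matching is exact.

### Matching

Matching is greedy and sequential: cases in ascending report-id order each
draw `ratio` non-cases uniformly at random, without replacement, from their
exact stratum, under a user seed (per-stratum Fisher–Yates stacks, so the
whole pass is linear in the pool). Greedy sampling is the standard practice
for case/non-case designs; optimal matching buys nothing when strata are
exact and disjoint, and on disjoint strata greedy succeeds exactly when a
complete bipartite matching exists (tested against a max-matching oracle).
Two infeasibility policies exist: `strict_drop` (drop and log the case,
recording its deficit) and `widen_age` (relax the age criterion stepwise ±1,
±2, … up to a cap, default ±5 years, then drop). Exact-age matching is the
default because realistic reporting databases populate every (age, sex, year)
stratum densely; the widening policy exists for small synthetic pools.

### Exposure and covariates

Exposure is report-level: a report is exposed iff any of its drugs carries a
qualifying role and an ATC code under a qualifying prefix (missing codes and
roles never match). The ATC hierarchy is prefix-closed, so classification is
plain string-prefix matching on upper-case codes. Defaults: statin prefixes
C10AA, C10BA, C10BX with role `suspected`; the first sensitivity scenario
widens roles to suspected-or-concomitant. The `interacting` role never counts
toward exposure.

Covariates are co-medication class flags counting drugs in any role. ATC
prefix sets are configuration data, not code; the shipped defaults follow WHO
ATC conventions (anti-arrhythmics C01B; antihypertensives C02, C03, C07, C08,
C09; antidiabetics A10; NSAIDs M01A; corticosteroids H02AB; antidepressants
N06A; antiepileptics N03A; acid inhibitors A02BA, A02BC; a DMARD substance
list; and non-statin lipid agents as C10 minus the statin prefixes, so the
partition of C10 is exact).

## Estimation

* **Crude ROR**: ad/(bc) on the 2×2 table implied by the matched cohort, with
  Woolf standard error √(1/a+1/b+1/c+1/d), log-normal CI, and a two-sided
  Wald p. With any zero cell the Haldane–Anscombe correction (0.5 to all four
  cells) is applied when opted in (`model.zero_correction`, default on);
  otherwise a zero cell is an error. Woolf CIs were chosen for the crude
  estimate because they are the Wald CIs of the saturated logistic model,
  keeping crude and adjusted intervals directly comparable.
* **Adjusted ROR**: unconditional maximum-likelihood logistic regression
  (Newton, tolerance 1e-10 on the iterate, 50 iterations max; standard errors
  from the observed information). The matching variables (age, sex as a
  female indicator, reporting year, all untransformed) are always forced into
  the adjusted model; conditional logistic regression is deliberately not
  used — the matched design is instead handled by covariate adjustment for
  the matching factors, which is the analysis the output tables of this
  study design report.
* **Confounder selection**: change-in-estimate. Each candidate is added
  singly to the crude model; it is retained iff the exposure coefficient
  moves by at least `threshold` (default 10%) in relative terms, and the
  adjusted model refits all retained candidates jointly. If the crude
  exposure coefficient is exactly zero the relative change is undefined and
  an absolute-change criterion of `threshold/10` is used with a warning.
  Candidates whose single-addition fit is rank-deficient or degenerate are
  skipped (logged), hence never selected. A rank check runs before every fit
  (QR with pivoting names the aliased terms); a coefficient magnitude above
  15 on the logit scale, or a perfect-prediction signal from the optimizer,
  flags quasi-separation on the returned fit rather than failing the run,
  and CI limits that overflow the exponential are reported as infinite.
* **Baseline tests**: Welch's t for continuous characteristics; for binary
  characteristics Pearson's chi-square without continuity correction when all
  expected cells are ≥ 5, otherwise the two-sided Fisher exact test. Tests
  are two-sided at α = 0.05; no multiplicity correction is applied anywhere,
  matching standard practice for descriptive baseline tables. Displayed
  percentages round half-up to one decimal.

Logistic fits are delegated to statsmodels' `Logit` (Newton ML); the ROR,
Woolf interval, selection loop, and all validation are implemented here.

## Sensitivity scenarios

Scenarios re-filter the primary matched cohort; they never re-match. This
keeps the non-case series fixed across scenarios that only change the case
definition or exposure role (scenarios 1, 4, 5 retain all 1,635 non-cases)
and lets restriction scenarios (physician reporters, age ≥ 50) act
symmetrically on both series, with the achieved — not forced — case:non-case
ratio reported. The age restriction is implemented as ≥ 50 (not > 50): the
under-50 stratum is what the restriction removes, and the 50-year-olds
remain; both the threshold and strictness are configurable. "Physician
reporters" maps to {general_practitioner, physician, specialist, hospital},
also configurable. A scenario whose filters leave no cases, or leave exposure
without variation, is skipped with a warning and the remaining scenarios
proceed.

## Synthetic data

No real ICSR data can ship with the package, so two generators stand in.

**Simulator** (`generate`). Draws exposure conditionally on outcome:

    logit P(exposed) = logit(p_exposure_noncase)
                       + log(true_or)·is_case + Σ log(or_with_exposure_j)·Z_j

with each binary confounder Z_j at its configured prevalence among non-cases
and oversampled among cases to hit its odds ratio with the outcome. The
outcome-conditional formulation mirrors the design itself and gives exact
control of the target ROR. Defaults are the study conditions of the source
population: 327 cases, ratio 5, mean age 67.7 (SD 11.0, integer ages
truncated to [18, 100] so exact-age strata are populated), 62.1% female,
reporting years 1990–2006, non-case exposure probability 0.029, true ROR 14,
no confounders. Case demographics are independent draws; the non-case pool is
emitted *stratified on the case strata* (`pool_multiplier × ratio` non-cases
copying each case's age/sex/year) rather than drawn independently — with
independent draws no finite pool can guarantee five eligible matches per
stratum, whereas the stratified pool makes 1:5 matching feasible by
construction, which is the premise of the matched-count checks. The simulator
does not attempt reporting-rate dynamics, co-prescription realism, or
country effects; passing tests demonstrate estimator correctness and
calibration under the stated generative model, not performance on real
reporting data with its underreporting and differential-reporting biases.

**Margins fixture** (`margins_fixture`). A seed-free dataset of 327 cases and
1,635 non-cases in pre-matched strata (each case shares its stratum with
exactly five non-cases) whose *marginal* counts — exposure by status and
role, age under 50, single-reaction-term cases, physician reporters, and the
descriptive profile of the 96 suspected-exposed cases — equal a published
statin–PMR disproportionality analysis. Attributes are assigned by
deterministic index blocks; sex is interleaved through the blocks (exactly
203 of 327 female) so that no attribute block is collinear with sex. Only the
margins are meaningful; joint distributions beyond the constrained ones are
an artefact of the block construction, which is why the fixture's adjusted
estimates are close to, but not equal to, its crude ones.

## Problem sizes

The calibration suite uses 200 replicates per regime at the full study scale
(327 cases, ratio 5) — about 2,000 reports per replicate with the default
pool — which completes in well under a minute; single-fit checks use up to
20,000 rows. The bipartite-matching oracle runs on instances of ≤ 8 cases and
≤ 40 pool members, where exhaustive verification is cheap.

## Known limitations

* Unconditional (not conditional) logistic regression; no Firth penalisation
  or Bayesian shrinkage (IC/EBGM) — quasi-separated scenario fits are
  flagged, not regularised.
* The crude estimator is exactly ad/(bc); published crude RORs that condition
  on additional structure (e.g. matched-set handling) will differ slightly.
* Preferred terms are opaque strings; no MedDRA/WHO-ART hierarchy traversal,
  and no drug-name→ATC dictionary (names are display-only).
* Exposure is report-level and binary: multiple statins, dose, and duration
  are not modelled.
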