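# Methods

This note documents the models and procedures behind `nbscreen`: what is
computed, what is assumed, which knobs matter, and what the synthetic cohort
does and does not emulate.

## The marker panel

The panel has 74 indicators: 43 measured channels — 11 amino acids, one
ketone (succinylacetone, SA), and acylcarnitine species from free carnitine
(C0) to C18:1OH — and 31 ratios derived from them. Concentrations are in
μmol/L; ratios are dimensionless. The non-derivatized MS/MS kit reports some
isobaric acylcarnitine pairs as a single combined channel
(`C3DC + C4OH`, `C4DC + C5OH`, `C5DC + C6OH`) and the leucine channel as
`LEU + ILE + PRO-OH`; these are single measured quantities and are never
synthesized by adding components. Ratios are always derived as
`sum(numerator)/sum(denominator)` over measured channels; a missing operand
or zero denominator leaves the ratio absent (logged), never NaN/inf — an
absent ratio must neither fire nor clear a rule.

The shipped config includes the ratio `(C4DC + C5OH)/C0` with reference
range 0–0.03. This ratio is an operand of the holocarboxylase-synthetase /
3-methylcrotonyl-CoA-carboxylase rule and its upper bound matches that
rule's `≥ 0.03` threshold; the bound is a design choice of this package, as
the source indicator list for this single row was incomplete.

Reference intervals are closed: a value inside `[low, high]` (bounds
included) is normal for `flag_out_of_range`. Rule thresholds, by contrast,
honor the printed comparator exactly: `PHE > 100` is *not* satisfied at
`PHE = 100`, while `PHE/TYR ≥ 1.4` is satisfied at 1.4.

## The rule engine and triage

Each of the 26 rule rows screens one disorder or a set of biochemically
indistinguishable disorders (e.g. methylmalonic and propionic acidemia; the
differential belongs to confirmatory testing, so one row flags one combined
label carrying all OMIM codes). A row is a disjunction of groups; a group a
conjunction of conditions. Within a printed cell, comma-separated conditions
are conjunctive; separate rule columns are disjunctive — the primary-
carnitine-deficiency row only makes sense this way (`C0 < 8.5` alone, OR
`C0 < 9.0` AND acylcarnitine-sum/CIT `≤ 1.3`). The alternative C3 rules
(`C3/C0 > 0.3`, `C3/C2 > 0.29`, `C3/MET > 0.4`) are treated as standalone
disjuncts; the medium-chain rule's `(C4DC + C5OH)/C8 ≤ 1` is conjunctive
with the rest of its cell. Conditions on absent markers evaluate false
(fail-safe for ratio-dependent groups; single-marker groups still fire).

Triage is three-way. "Clear aberrant" first screens are referred for
confirmatory testing immediately, without recall; the quantitative boundary
is this package's interpretation, not an observed program parameter: a
record is clear-aberrant when some satisfied condition exceeds *k*-fold of
its threshold (`value > k·threshold` for upper-tailed conditions,
`value < threshold/k` for lower-tailed), with `k = 2` by default,
configurable via `TriagePolicy`.

## Fixture completion for confirmed cases

The confirmed-case fixtures print only each case's abnormal markers. For
rule evaluation the unprinted measured markers are completed with the
*reference median* — the median of the calibrated lognormal reference
population, which equals the geometric mean `sqrt(low·high)` of the
reference bounds — and ratios are then derived, with printed ratio values
taking precedence. The geometric mean, not the arithmetic midpoint, is the
representative central value for right-skewed analytes; with arithmetic
midpoints several genuinely screen-positive cases become unflaggable by
arithmetic alone (e.g. a citrullinemia case at CIT 39.0 needs ALA/CIT < 9.5,
and the midpoint ALA of 387.5 gives 9.94, while the median 285.0 gives 7.3).

Under this completion, 59 of the 63 laboratory-confirmed cases flag a
screening label containing their diagnosis. The four exceptions are
arithmetic facts of the printed values, asserted as such in the tests: a
phenylalanine of 105.43 (above the 100 threshold but below 120, with the
conjoined PHE/TYR condition unsatisfiable at a typical TYR); the citrin-
deficiency case with CIT 25.83, inside the reference range — a documented
primary-screen false negative, later diagnosed clinically; a VLCADD case
whose printed markers (C12, C14, C18) are not operands of the VLCADD rule
(which keys on C14:1); and a MADD case whose rule requires the unprinted C4.

## Synthetic cohort model

**Marginals.** Each measured marker is lognormal, with `(μ, σ)` solved in
closed form so that the reference bounds sit at quantiles `q_low`/`q_high`
(defaults 0.5%/99.5%, configurable — the laboratory's ranges are treated as
population quantiles as an assumption, not established fact). A zero lower
bound is replaced by `min(high/1000, 0.001)`. Ratios are never sampled.

**Dependence.** All log-concentrations of a specimen share one common
standard-normal factor with exchangeable correlation ρ: blood-spot punch
volume, hematocrit and extraction efficiency scale every analyte of a
specimen together, and the shared factor partially cancels in every ratio.
This is what makes laboratory ratio reference intervals much narrower than
independent per-marker variation would imply: under independence the C3/C2
log-sd would be 0.72 against the 0.37 implied by its printed range, and
unaffected cohorts would flag ≈15% of newborns. ρ is fitted once by least
squares of modeled vs range-implied log-sd over all single-marker/single-
marker ratios (fitted value 0.464 for the shipped panel; SSE 0.157 vs 0.198
for the median-of-implied-ρ alternative). Marker marginals are unaffected by
ρ; setting `marker_correlation = 0` recovers fully independent sampling.

**Disease profiles.** Affected newborns are drawn per disorder at the
configured incidence (defaults: the program's observed rates, e.g. primary
carnitine deficiency 22/300,849). A profile targets one rule group —
preferring groups free of ratio conditions — and samples each condition's
marker uniformly between its threshold and the most extreme value printed
for a confirmed case of that disorder (fallback 3× threshold, or
threshold/3 for lower-tailed conditions). Ratio conditions are met by
rescaling the ratio's numerator operands to a uniformly drawn target ratio;
the group is re-verified on derived values and resampled on the rare
interaction failure. `sensitivity` is the probability an affected newborn
expresses the profile at all; otherwise its panel is drawn from the
unaffected population (a biochemical false negative, as observed for one
citrin-deficiency case).

**False-positive layer.** With probability `fp_rate` an unaffected newborn
has one randomly chosen measured rule marker pushed just past its threshold
(uniform in `(threshold, 1.2·threshold)`, mirrored for lower-tailed
conditions). The default is 0: with the quantile-anchored marginals the
reference-tail false positives alone (notably the hyperprolinemia rule
`PRO > 340`, which lies *inside* the 75–420 reference range and fires on
≈2.6% of unaffected newborns) already exceed the program's observed 1.64%
suspected-positive fraction, so `fp_rate` only adds to an already
conservative baseline. The suspected fraction increases monotonically with
`fp_rate`; this is asserted as a property.

**What the generator does not emulate.** Realistic analytical noise,
gestational-age/birth-weight/feeding covariates, specific marker-pair
correlations beyond the exchangeable factor, seasonal or secular drift, and
the program's true false-positive mechanism. Passing tests therefore show
that the pipeline arithmetic, classifier and funnel are correct under the
stated statistical model — not that the model matches real dried-blood-spot
data; in particular the simulated suspected-positive volume (≈7%) is several
times the program's observed 1.64%.

## Two-tier workflow

Clear-aberrant first screens skip recall and are referred directly; mild
positives are recalled with probability `recall_prob` (non-recalled newborns
are lost and never diagnosed; confirmed ≤ recalled always). At retest,
affected cases re-flag with `tp_persist`, unaffected with `fp_persist`.
Confirmatory testing (urine organic acids, pterin analysis, DHPR activity,
sequencing) is collapsed into one Bernoulli step with sensitivity
`confirm_sens` and specificity 1 — no per-test operating characteristics are
available, and perfect specificity makes simulated diagnoses a subset of the
truly affected, asserted per run. Reported recall rates count directly-
referred clear-aberrant newborns as successfully recalled (they return for
confirmatory sampling), so the recall denominator is all suspected
positives, matching program bookkeeping.

## Reporting arithmetic

Incidence strings are `1:N` with `N = screened/cases`; the disorder/category
summary rounds N half away from zero (forced by `300,849/2 → 1:150,425`),
while yearly program reports truncate (`59,439/20 → 1:2,971`); both modes
are exposed and the summary/yearly functions apply the appropriate default.
Percentages are rounded half-up to 2 dp and use the total confirmed count
(71) as denominator. Two printed category percentages in the source program
report (16.66% and 43.05%) are inconsistent with their own counts over 71;
this package computes from counts (16.90%, 43.66%).

Mutation-spectrum counting is one count per detected allele slot, grouped by
(gene, nucleotide HGVS) with case/whitespace folding only — HGVS strings are
never normalized or validated, and pathogenicity labels are carried through
as annotation. The canonical shipped fixture is the published 118-allele
count table; the raw per-case genotype tables disagree with it by single
alleles for two genes (36 vs 37 *SLC22A5* alleles; one vs two *PAH*
c.498C>G), so the count table is authoritative and the genotype route is
exercised separately. Relative frequencies may pool genes into one disease
denominator (*PAH* + *PTS* → hyperphenylalaninemia, 24 alleles), which is
required to reproduce the published within-disease frequencies.

## Problem sizes and statistical test design

The test suite and acceptance script use the program scale (n = 300,849) for
pipeline recovery: 10 replicate cohorts for incidence recovery, with each
disorder's pooled confirmed count tested against its pooled Poisson interval
(Bonferroni-corrected across the 15 disorders for family-wise 95% coverage —
a single-cohort, per-disorder 95% check would fail roughly half of all seeds
by construction); 20 replicate cohorts for the recall-rate calibration
(±1 point of 87.65% at `recall_prob = 0.8765`); 10⁵ draws for Monte-Carlo
quantile checks (5% relative tolerance); 100 random panels for the
ratio-oracle and rule-brute-force equivalences (10⁻¹² relative tolerance for
ratios, exact for flags).

## Known limitations

- Disorder coverage of the synthetic default profiles is the 15 disorders
  confirmed by the program; the other rule rows are exercised by random-panel
  and fixture tests only.
- The clear-aberrant boundary, workflow probabilities and per-disorder
  screening sensitivities are free parameters, not estimates; the program
  published no values for them.
- Incidence configuration treats the observed case counts as true rates;
  with 71 cases total, recovered per-disorder rates are dominated by Poisson
  noise at single-program scale.
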