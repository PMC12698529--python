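# Methods

`pvalopecia` implements a spontaneous-report signal-detection pipeline for
drug-induced alopecia and exercises it end to end on a synthetic
FAERS-like generator with known ground truth. This note records the models,
the defaults and why they were chosen, what the simulations do and do not
show, and the numerical decisions a maintainer would want written down.

## Ingestion and de-duplication

FAERS quarterly extracts are `$`-delimited ASCII tables keyed by PRIMARYID
(report version) and CASEID (safety case). The reader treats empty fields as
missing, skips (and counts) rows with the wrong field count, and hard-fails
only on a malformed header. De-duplication keeps, per CASEID, the version
with the latest FDA receipt date, breaking ties by the highest PRIMARYID; a
version with an unparseable FDA_DT ranks below every dated version, so an
audit-dated report always wins. The operation is idempotent and never
invents rows.

Partial dates (YYYY, YYYYMM, YYYYMMDD) carry an explicit precision tag.
Ordering between mixed precisions completes to the earliest possible day —
for ordering only; time-to-onset arithmetic requires day precision on both
ends.

Unit conversions are exact constants: age DEC×10, YR×1, MON÷12, WK÷52,
DY÷365.25; weight LBS×0.4536. Values outside [0, 130] years or (0, 700) kg
are treated as missing rather than clipped. A case is "serious" iff it
carries at least one regulatory outcome code (DE/LT/HO/DS/CA/RI/OT); the
severity dichotomy in baseline tables follows from that definition.

## Case definition

Alopecia cases are flagged by exact, case-insensitive preferred-term match
against a narrow-scope SMQ term list. Substring matching is deliberately not
offered: MedDRA PTs are a controlled vocabulary and substrings over-match
("Alopecia" would capture "Alopecia scarring"). The packaged seed list holds
thirteen publicly named alopecia PTs; MedDRA itself is licensed, so users
must substitute the official SMQ for real analyses.

Drug attribution defaults to Primary Suspect entries only: a report listing
the drug as Secondary Suspect, Concomitant or Interacting does not count
toward the drug's exposure cell, and each de-duplicated case contributes at
most once per drug with no weighting for co-medication. This trades
sensitivity for specificity. Drugs indicated for alopecia itself
(minoxidil-class, 5-alpha-reductase inhibitors, JAK inhibitors) are removed
after signal screening via a configurable exclusion list, because their
"signals" are contaminated by treatment-failure reports.

## Disproportionality statistics

For drug D and the alopecia event over N de-duplicated cases, the 2×2 cells
are a (D and event), b (D, other events), c (event, other drugs), d (rest);
E = (a+b)(a+c)/N is the expected overlap under independence.

* **ROR** = ad/bc, Woolf interval exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
* **PRR** = [a/(a+b)]/[c/(c+d)]; the accompanying χ² is the Pearson 2×2
  statistic without continuity correction; the Yates variant is behind a
  flag. (Either convention is seen in the disproportionality literature;
  Pearson is the default because the joint rule's χ² ≥ 4 threshold is
  conventionally quoted uncorrected.)
* **BCPNN IC** = log2((a+½)/(E+½)), with the Norén closed-form bound
  IC025 = IC − 3.3(a+½)^−1/2 − 2(a+½)^−3/2. The closed form is
  deterministic and accurate for the credibility bound; an unshrunk
  log2(a/E) variant and a seeded Monte-Carlo interval (gamma-posterior
  draws of the shrunk observed-to-expected ratio) are available behind
  flags.
* **MGPS EBGM**: DuMouchel's empirical Bayes model. The Poisson rate ratio
  λ has a two-gamma mixture prior with five hyperparameters
  (α₁,β₁,α₂,β₂,p) fitted to the whole database by maximum marginal
  likelihood — each drug contributes (a, E), the marginal is a mixture of
  negative binomials, and optimisation runs L-BFGS-B on log/logit-
  transformed parameters from the classic start (0.2, 0.1, 2, 4, 1/3) plus
  seeded random restarts. The posterior is again a two-gamma mixture, so
  EBGM = exp E[ln λ | a] is a digamma expression and EBGM05 is found by
  bracketed root-finding on the mixture CDF (bracketing from zero, where
  the CDF is exactly 0, is robust to near-degenerate fitted components
  that pile mass at the origin).

Zero cells make ROR/PRR undefined; the result is a NaN marker, never an
exception, and a NaN statistic fails its positivity flag. An optional
Haldane–Anscombe +0.5 correction exists for ROR/PRR only — IC and EBGM are
already shrunk and need none.

A drug is a **signal** only when all four methods fire simultaneously, with
the conventional FAERS screening thresholds (all configurable): a ≥ 3 and
ROR lower bound > 1; a ≥ 3, PRR ≥ 2 and χ² ≥ 4; IC025 > 0; EBGM05 > 2.
The conjunction is deliberately conservative: in the all-null calibration
study (200 drugs, 100,000 synthetic cases) it produces zero positives.

Volcano coordinates are two-sided Fisher exact p-values (Bonferroni-adjusted
over the number of drugs tested) against ln ROR; a +0.5 correction is
applied to the axis value only when a cell is zero so the axis stays finite.

## Stratification, tiers, labels

Subgroups use age bands <18, 18–44, 45–64, ≥65 (left-closed; integer-aged
data make the open/closed choice immaterial at the printed boundaries) and
sex F/M; cases missing the stratifying field fall outside the stratum. Each
stratum rebuilds its population, event set and 2×2 cells from stratum
members only — stratum-restricted comparators, the more conservative of the
two defensible choices. A drug-category stratum instead keeps all cases and
restricts which drugs are evaluated (via a drug → category CSV). The
Bonferroni family is the number of drugs evaluated within the stratum;
"lost significance" marks raw p < 0.05 with adjusted p ≥ 0.05. Narrow
strata should share the whole-database MGPS prior rather than fit their
own.

Risk tiers cut on the BCPNN credibility bound: high IC025 > 3, medium
1.5 < IC025 ≤ 3, low IC025 ≤ 1.5 (boundary values fall down). Applied to the
bundled 64-drug reference signal table this yields 6/26/32.

Label cross-checking consumes a curated drug → documented CSV; the packaged
annotation file is synthetic (see its docstring) and reproduces the
reference 49 documented / 15 undocumented split. Percentages round half-up —
at the presentation layer only; raw values are retained in all outputs.

## Time-to-onset

TTO is the whole-day span from the earliest day-precision Primary-Suspect
start date of the drug in a case to the day-precision event date; negative
spans and partial dates are excluded with counts logged. Quartiles use the
median-of-halves convention (halves exclude the middle observation when n is
odd), which reproduces single-observation summaries (n=1 → Q1=median=Q3).
Histograms use half-open 30-day bins to 240 days, then 240–360 and >360,
capturing the two clinically expected latency regimes (acute anagen
effluvium within a month; telogen effluvium emerging after months).

Weibull fits are uncensored maximum likelihood via lifelines'
`WeibullFitter` (shape β, scale η days, normal-approximation CIs;
median = η·ln2^(1/β)). Zero-day onsets are kept in summaries but shifted by
+0.5 day (half the recording resolution) for the likelihood, whose support
is positive. Fits require n ≥ 10 with ≥ 2 distinct values; below the floor
the per-drug summary row is still emitted with NaN fit columns. Recovery
simulations (200 replicates, n=500, day-rounded draws) show mean shape bias
below 0.03 across β ∈ {0.5, 1, 2}. No censoring model is attempted:
spontaneous reports carry no at-risk denominators.

Group comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration when the pooled sample is ≤ 12 and tie-free, otherwise the
tie-corrected normal approximation (which agrees with the exact p within
0.02 at n=6 per group).

## Synthetic generator

Each synthetic case draws one Primary-Suspect drug, reports the alopecia
event with probability min(1, base_rate·RR(drug)), carries one or more
background PTs, and receives a latency from the drug's Weibull encoded as
start/event dates. Defaults emulate a large alopecia report population:
76.82% female and 13% unknown sex, age 53.84 ± 16.28 years with 41.42%
missing, 71.53% missing weight, 46.69% serious, US-dominated reporting, and
a target-event background rate of 0.008 (the approximate share of alopecia
reports in a two-decade FAERS extract). Missing (30%) and month-precision
(10%) start dates exercise the partial-date paths; both rates are design
choices at realistic magnitudes rather than estimates of any particular
database. Duplicate case versions (5%) emit an older DEMO row with its own
DRUG/REAC rows, so a de-duplication failure changes downstream counts
instead of silently vanishing. A polypharmacy mode adds Concomitant-role
drugs that must never enter PS-only indexes. Output is byte-identical under
a fixed seed.

The generator emulates the *structure* of spontaneous-report data, not its
pathologies: drug names are clean (no free-text noise beyond an optional
synonym map), reporting rates are stationary over calendar time, and
demographics are independent of drug and event. Passing calibration here
shows the statistics and plumbing are correct, not that real-database
confounding (stimulated reporting, masking, channeling) is handled.

The packaged end-to-end fixture plants 71 strong signal drugs (RR 55–75,
named after a published 64-drug alopecia signal roster plus 7
alopecia-treatment drugs) among 400 drugs over 40,000 cases. The planted
rates are deliberately large: with 71 of 400 drugs elevated, the background
event rate inflates to ≈0.095, which caps the achievable observed/expected
ratio near 400/71 ≈ 5.6 and would starve the EBGM05 > 2 criterion at
moderate RR. The fixed-seed fixture yields exactly 71 joint-rule positives,
and excluding the 7 indicated drugs leaves 64.

## Coverage estimand

The planted-effect study checks the ROR interval against the generator's
*implied odds ratio*, exposed as `GroundTruth.implied_odds_ratio`: the
event odds under the planted drug versus the mixture odds over the other
drugs. With base rate 0.008 and RR=10 the implied OR is 10.78 — the ROR
estimates the odds ratio, not the rate ratio, and the two separate whenever
the event probability is non-negligible. Coverage of the implied OR runs at
the nominal ~95% (93–97% observed over 100-replicate batches); detection
(joint rule) is 100% at a ≈ 80.

## Known limitations

* The MGPS prior refitted to 5,000 simulated pairs reproduces posterior
  EBGMs of co-reported pairs (a ≥ 1) to within 10% on average, but a = 0
  pairs are prior-dominated and their EBGM is unidentifiable at the pair
  level: refits with *better* marginal likelihood than the truth can move
  zero-count EBGMs by >50%. Joint-rule decisions are unaffected (a = 0 can
  never reach the a ≥ 3 floor).
* Stratified MGPS uses per-stratum priors; Mantel–Haenszel pooling of
  expected counts across strata is not implemented.
* Only PRIMARYID-keyed (2012+) file layouts are supported; legacy ISR-keyed
  files are not.
* PT-level analysis stays at the preferred-term level; no MedDRA hierarchy
  traversal.
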