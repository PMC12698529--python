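# pvalopecia

Pharmacovigilance signal detection for drug-induced alopecia in
FAERS-style spontaneous report data.

Drug-induced hair loss is common, distressing, and — because latency
ranges from days (cytotoxic anagen effluvium) to many months (telogen
effluvium) — easy to misattribute. Spontaneous-report databases such as
FAERS let us screen hundreds of drugs for disproportionate alopecia
reporting, but doing that defensibly requires a chain of unglamorous steps:
de-duplicating report versions, defining cases through a controlled MedDRA
term list, restricting attribution to Primary-Suspect drugs, computing
several disproportionality statistics with different shrinkage behaviour,
adjusting subgroup comparisons for multiplicity, and modelling
time-to-onset. This package implements that chain as a tested library with
a CLI, plus a synthetic FAERS-like generator with planted ground truth so
every stage can be validated offline.

It is written for pharmacoepidemiologists and biostatisticians who want a
transparent, configurable reference implementation rather than a black box.

## The statistics

For each drug, over N de-duplicated cases, the standard 2×2 table
(a = drug & event, b = drug & other events, c = other drugs & event,
d = rest; E = (a+b)(a+c)/N) feeds four methods:

| method | statistic | signal criterion (defaults) |
|---|---|---|
| ROR | ad/bc, Woolf 95% CI | a ≥ 3 and CI lower bound > 1 |
| PRR | [a/(a+b)]/[c/(c+d)], Pearson χ² | a ≥ 3, PRR ≥ 2, χ² ≥ 4 |
| BCPNN | IC = log2((a+½)/(E+½)), Norén IC025 | IC025 > 0 |
| MGPS | EBGM = exp E[ln λ \| a] under DuMouchel's two-gamma prior | EBGM05 > 2 |

A drug is a **signal** only when all four fire simultaneously — a
deliberately conservative conjunction (zero false positives in a 200-drug
all-null calibration). Signals are then tiered on IC025 (high > 3,
medium 1.5–3, low ≤ 1.5), stratified by sex and age band with per-stratum
Bonferroni adjustment, and cross-checked against label documentation.
Time-to-onset per drug is summarised (median/quartiles, 30-day bins) and
modelled with a maximum-likelihood Weibull whose shape separates
early-failure from wear-out hazards.

## Worked example

Simulate a database with one drug planted at ten times the background
alopecia reporting rate, then screen it:

```bash
pv simulate -o sim --n-cases 4000 --n-drugs 10 --seed 5 --planted DRUG_000=60
pv signal -i sim -o signals.csv
```

which prints

```
wrote 5 tables to sim
1 positive of 10 drugs -> signals.csv
```

`signals.csv` holds one row per drug with the 2×2 cells, all four
statistics with their bounds, Fisher/Bonferroni p-values, per-method flags
and the joint verdict. The planted drug is the single positive and ranks
first by ROR.

The `analysis/` scripts run the full study on the packaged 40,000-case
fixture (71 planted signal drugs among 400, 7 of them alopecia-treatment
drugs that the exclusion step removes). For example `python
analysis/03_signals.py` prints:

```
400 drugs screened, 71 joint-rule positives, 64 after excluding 7 condition-indicated drugs
rank correlation between recovered ROR and planted RR: 0.77
```

and `python analysis/05_time_to_onset.py` recovers a planted latency
distribution:

```
SPINOSAD: fitted shape 0.99 (planted 1.0), scale 137 d (planted 135), median 89 d, n=57
```

A YAML-configured end-to-end run (`pv run -c config.yaml`) writes tidy CSVs
for every stage plus a manifest with input checksums and the case-count
funnel; see `pvalopecia.pipeline.RunConfig` for every threshold and toggle.

## Bundled reference data

Small packaged CSVs (see `pvalopecia.datasets`): a seed narrow-scope
alopecia SMQ term list (13 publicly named PTs — substitute the licensed
MedDRA SMQ for real analyses), a 64-drug reference signal table with
therapeutic categories and IC025 values used for bookkeeping examples, a
*synthetic* label-annotation file reproducing a 49/15
documented/undocumented split, and per-drug reference time-to-onset
summaries.

## Layout

```
src/pvalopecia/      library: faers_io, case_definition, disproportionality,
                     stratification, tto_analysis, synthetic_data,
                     calibration, pipeline, cli, datasets (+ packaged data/)
analysis/            numbered narrative drivers over the library
tests/               pytest suite incl. property tests and oracle checks
scripts/acceptance.py
docs/methods.md      model details, defaults, numerical decisions, limits
```
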