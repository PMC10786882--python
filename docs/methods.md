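# Methods

## Study design

The package implements a retrospective case/non-case design over a
spontaneous reporting database in the FAERS quarterly ASCII format. The
unit of analysis is the individual case safety report (ICSR). The exposure
of interest is secukinumab as a primary or secondary *suspect* medication;
the two comparator exposures are (a) the other biologics approved for
psoriasis (adalimumab, brodalumab, certolizumab, etanercept, guselkumab,
infliximab, ixekizumab, risankizumab, tildrakizumab, ustekinumab) and
(b) the systemic non-biologics (acitretin, apremilast, cyclosporine,
methotrexate). A report enters the cohort only when a suspect catalog drug
carries one of five indication preferred terms: psoriasis, guttate
psoriasis, pustular psoriasis, nail psoriasis, erythrodermic psoriasis.
Indication matching is exact (case-insensitive) PT equality — substring
matching would wrongly capture e.g. "psoriatic arthropathy".

The secukinumab group is exclusive and takes precedence: a report
suspecting secukinumab belongs to it regardless of other anti-psoriatic
suspects. The two comparator groups may overlap (a report can suspect both
a biologic and a non-biologic), so comparator sizes can sum to more than
the cohort size. A lenient indication mode (term accepted anywhere in the
report) is available behind a flag; strict drug-level matching is the
default because the design ties the indication to the suspected medication.

## Deduplication

Two stages, in fixed order:

1. **Case-version dedup** — FAERS assigns each report a primary id =
   case id ‖ case version; only the latest version per case id is kept.
   Version ties (contract violations, tolerated) break by latest FDA
   receipt date, then smallest primary id.
2. **Multifield dedup** — reports re-entered under different case ids are
   collapsed when they match exactly on: event date, age (value and unit,
   as reported, no unit conversion), sex, reporter country, suspect drug
   set, and reaction term set. Drug names in the key are
   catalog-canonicalized (brand/generic variants of one drug match);
   reaction terms are case-folded and set-compared. The cluster survivor is
   the record with the latest FDA receipt date (most complete/corrected),
   ties by smallest primary id.

Missing key fields compare equal under the default `missing_matches`
policy (conservative toward removing duplicates); `missing_never_matches`
exempts any record with a missing key field from collapsing. Every removal
is written to an audit log (removed id, survivor id, stage). Probabilistic
record linkage is out of scope.

## Disproportionality

PRR and ROR are computed per term at three MedDRA levels. SOC-level event
sets are all PTs whose *primary* SOC is the term (a PT maps to exactly one
primary SOC); SMQ-level sets are the level-1 narrow-scope members; PT-level
sets are singletons. A report with several PTs inside one SOC/SMQ counts
once for that term. PT-level terms require ≥ 100 exposed reports by
default (SOC/SMQ: ≥ 1); the threshold is configurable, and the package's
own simulations lower it deliberately when group sizes are in the
thousands rather than the tens of thousands.

CI construction uses the log-normal (Woolf, for ROR) variance formulas
with z = 1.96 as written in the standard pharmacovigilance formulation;
tests cross-check against statsmodels' `Table2x2`, which differs only by
its use of the exact 0.975 normal quantile (≈ 0.1% in the bounds). Zero
cells leave the affected statistic undefined and flagged — never a
fabricated signal; an optional `halves` policy adds 0.5 to all four cells
when any is zero. No multiplicity adjustment is applied, matching standard
practice for hypothesis-generating screens.

## Descriptive summaries

Continuous variables are reported as median (IQR) with the inclusive
linear-interpolation quantile convention (numpy's `linear` method — the
spreadsheet default; medians/IQRs depend on the convention, so it is
pinned). Age statistics use only reports with age recorded in years; other
units (decades, months, days…) are excluded from age statistics, not
converted, and the records are retained everywhere else. Each
serious-outcome code on a report counts once toward that outcome, so
outcome tallies can sum to more than the group size. Onset latency is the
event date minus the earliest therapy start date among the target drug's
entries, requiring day precision on both sides; negative latencies are
excluded and tallied. Percentages are rendered by a round-half-up
formatter with a per-table decimals setting, and every printed percentage
is recomputable from its stored numerator and denominator. (When applied
to the published study group of n = 44,761, counts 949/6,591/14/11
reproduce the printed 2.1/14.72/0.03/0.02%; two of that table's other
printed figures — 1.30% from 586 and 33.42% from 14,962, as well as the sex
percentages 56.49/38.35/3.94 against their own counts — are not consistent
with half-up rounding of their printed counts, so this package always
reports the value recomputed from counts: 1.31, 33.43, 57.70/38.36/3.95.)

## Synthetic corpus generator

The generator emulates the statistical structure the design assumes, not
the marginal messiness of real FAERS. Per underlying case it draws: a
quarter (2015Q1–2021Q4 by default), FDA receipt and event dates inside it,
age ~ N(54, 13²) years clipped to 18–95, sex (56.5% F / 38% M), reporter
country, a suspect drug set by independent per-drug prevalence draws
(defaults shaped so the three groups split roughly 17% / 56% / 26%), one
of the five psoriasis indication terms per suspect drug, therapy start
dates with log-normal onset latency (median 92 days), serious-outcome
codes, reporting channel and reporter occupation.

Event terms are drawn per PT with a background probability (0.02 for each
of the 40 mini-dictionary PTs by default). A designed association
(drug, PT, target ROR) tilts the event odds multiplicatively for exposed
reports — exposed odds = target ROR × background odds — so the *expected*
unique-case 2×2 table has exactly the requested reporting odds ratio; the
true PRR is then derivable from the ledger. A derived probability reaching
1 is a configuration error naming the pair. Reports that would otherwise
have no reaction receive a filler PT ("Drug ineffective"), which is absent
from the dictionary and excluded from rankings, and does not perturb any
designed pair's table.

Duplicates mirror the two dedup stages: extra versions of a case (later
version changes only the receipt date — nothing in the dedup key) and
cross-source duplicates (new case id, identical key fields, later receipt
date, different reporting channel). The **truth ledger** records, per case,
the suspect drugs, event PTs, duplicate family, and the multifield key; it
can therefore recompute any true 2×2 table and the exact expected survivor
count of the two-stage dedup — including the (rare, legitimate) merges of
distinct cases that are genuinely indistinguishable on the key. The ledger
recomputes keys from its own stored fields, independently of the dedup
module.

What the generator does **not** emulate: real FAERS drug co-prescription
structure, country mix, free-text drug-name noise beyond brand/generic
variation, LLT-level coding, or reporting-rate secular trends. Passing
tests therefore demonstrate correctness of the pipeline's logic and
calibration of its statistics under the designed sampling model — not
robustness to every artefact of the real corpus.

`sample_association_table` draws single 2×2 tables directly from the same
designed binomial structure (exposed odds tilted over a background rate)
without file I/O; the coverage and null-calibration studies use it at
exposed n = 5,000 / comparator n = 20,000 / background 0.02 over 200
replicates (coverage) and 100 replicates × 50 candidate PTs (null rate,
minimum exposed count 5). Full-scale runs at the published corpus size
(365,590 reports) are intentionally not part of the test suite; simulation
sizes of 400–10,000 cases exercise every code path and keep the suite fast.

## Numerical and formatting choices

- All randomness flows from one integer seed through
  `numpy.random.default_rng`; corpus generation and the full pipeline are
  byte-deterministic (two runs produce identical files).
- Result ordering is fully specified: descending ROR, ties by descending
  exposed-event count, then term text; undefined RORs sort last.
- Partial dates (YYYY, YYYYMM) are kept at reduced precision; comparisons
  needing day precision treat them as missing. Invalid date strings become
  missing.
- Malformed input rows (wrong field count from stray `$` delimiters) go to
  a rejects report with line numbers; the pipeline proceeds. Child-table
  rows whose primary id has no DEMO row are reported as orphans.
- Dictionary and drug-name matching is case-insensitive and
  whitespace/punctuation-normalized, with no fuzzy matching.

## Known limitations

- The dedup key uses suspect-role drugs only; using all drugs is a
  plausible alternative reading of "suspect drugs" in multifield matching.
- ROR/PRR variance formulas assume independent reports; duplicates missed
  by exact-key matching inflate precision.
- The mini dictionary is synthetic: term-to-SOC assignments are arbitrary,
  and SMQ memberships are random subsets. It validates mechanics, not
  clinical groupings.
- Signal thresholds (PRR > 2, ROR > 2, CI low > 1) are conventions; no
  multiplicity control is applied by default (a Bonferroni annotation
  could be added downstream from the exported tables).
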