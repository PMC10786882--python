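# faers-signal

A case/non-case disproportionality analysis pipeline for spontaneous
adverse-event reports in the FAERS format, built around the study design
used to profile the safety of secukinumab (an anti-IL-17A monoclonal
antibody) in psoriasis: ingest the quarterly multi-table ASCII files,
deduplicate aggressively, restrict to reports where a suspect drug is a
systemic psoriasis therapy, and compare the reporting frequency of each
adverse-event term for secukinumab against other anti-psoriatic biologics
and against non-biologic systemic agents.

## Who this is for

Pharmacovigilance analysts and pharmacoepidemiology researchers who want a
tested, reproducible implementation of the standard frequentist
signal-detection workflow — and a synthetic FAERS-format corpus generator
with known ground truth, so every stage can be validated without
downloading the multi-gigabyte FAERS corpus or licensing MedDRA.

## The statistics

For one event-term set and one comparator group, the 2×2 report-count
table is

|                         | event of interest | all other events |
|-------------------------|------------------:|-----------------:|
| medication of interest  |         A         |        B         |
| comparator medications  |         C         |        D         |

with the two classic disproportionality measures:

- **PRR** (proportional reporting ratio) = (A/(A+B)) / (C/(C+D)),
  95% CI = exp(ln PRR ± 1.96·√(1/A − 1/(A+B) + 1/C − 1/(C+D)))
- **ROR** (reporting odds ratio) = (A/B)/(C/D) = AD/BC,
  95% CI = exp(ln ROR ± 1.96·√(1/A + 1/B + 1/C + 1/D)) (Woolf)

A drug–event pair is a **signal** when PRR > 2 and ROR > 2 and the ROR 95%
CI lower bound > 1 (strict inequalities). Signals are hypothesis-generating,
not causal. Analyses run at three MedDRA levels: preferred term (PT),
primary system organ class (SOC), and Standardised MedDRA Query (SMQ,
level-1 narrow-scope members); PT-level terms enter only when reported in
at least 100 exposed reports (configurable).

## Worked example

Simulate a 5,000-case corpus with both FAERS duplicate mechanisms and one
designed association (secukinumab → oral candidiasis, true ROR 4.0), then
run the full study:

```python
import faers_signal as fs
from faers_signal.simulate import write_mini_meddra

sim = fs.SimConfig(n_cases=5000, seed=42,
                   version_dup_rate=0.3, crosssource_dup_rate=0.1,
                   injected_associations=[("secukinumab", "Oral candidiasis", 4.0)])
fs.generate_corpus(sim, out_dir="demo/data")
pt, smq = write_mini_meddra("demo/dict", seed=42)

rc = fs.RunConfig(input_globs=["demo/data/*.txt"], pt_soc_table=pt,
                  smq_table=smq, min_exposed_reports=5, output_dir="demo/out")
artifacts = fs.run_study(rc)
print(artifacts.manifest["stages"])
```

The manifest records the attrition funnel — 8,507 raw report rows
assembled, 5,515 after keeping the latest case version, 5,000 after
multifield deduplication (exactly the number of underlying cases), of
which 1,224 suspect secukinumab, 2,724 other biologics, and 1,505
non-biologics (comparator groups may overlap; the secukinumab group is
exclusive). The top of the PT-level results table against non-biologics:

```
            term level    comparator   a    b  c    d    prr ...    ror ror_ci_low ror_ci_high signal
Oral candidiasis    PT non_biologics 102 1122 26 1479 4.8237 ... 5.1713     3.3387      8.0098    yes
      Erysipelas    PT non_biologics  35 1189 22 1483 1.9561 ... 1.9843     1.1578      3.4006     no
```

The injected pair is recovered as the only signal (estimated ROR 5.17, 95%
CI 3.34–8.01, covering the designed 4.0); background terms like erysipelas
fail the PRR > 2 / ROR > 2 rule. The group summary reports, e.g., a median
onset latency of 91 days (IQR 45–197) from therapy start to event and a
death-outcome percentage of 2.6% in this simulated group.

The same workflow is scriptable from a shell via the `faers-signal` CLI
(`simulate`, `run`, `dispro`, `summarize` subcommands).

## Layout

- `faers_signal.faers_io` — dollar-delimited table parsing, ICSR assembly,
  serialization, rejects reporting
- `faers_signal.meddra` — PT→primary-SOC map and SMQ membership from open
  TSV interchange tables (MedDRA itself is licensed)
- `faers_signal.dedup` — latest-case-version retention and multifield
  duplicate collapsing, with an audit log
- `faers_signal.cohort` — drug-name normalization, psoriasis-indication
  filtering, three-group assignment
- `faers_signal.dispro` — contingency tables, PRR/ROR/CIs, signal rules,
  per-level analysis
- `faers_signal.summary` — demographics, outcome tallies, reporting
  channels, yearly counts, onset latency, common-term rankings
- `faers_signal.simulate` — synthetic FAERS-format corpora with a
  ground-truth ledger, plus a synthetic mini dictionary
- `faers_signal.pipeline` / `faers_signal.cli` — end-to-end orchestration
  and the command-line interface

See `docs/methods.md` for the modelling assumptions and design choices.
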