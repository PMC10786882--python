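"""Synthetic FAERS-format corpora with known ground truth.

The generator emits the seven dollar-delimited quarterly tables for a
configurable number of underlying cases, together with a *truth ledger*
recording, per case: the suspect drugs, the event PTs, and any duplicate
records derived from it. Every downstream stage is therefore testable
without downloading FAERS or licensing MedDRA:

* **Designed associations** — for an injected (drug, PT, target ROR)
  triple, the event probability among reports exposed to the drug is
  tilted on the odds scale (exposed odds = target ROR x background odds),
  so the expected unique-case 2x2 table has exactly the requested
  reporting odds ratio. The true PRR is then computable from the ledger.
* **Two duplicate mechanisms** mirroring the two dedup stages: extra
  *versions* of the same case id (later version changes only the receipt
  date, nothing in the dedup key), and *cross-source* duplicates (a new
  case id with identical key fields and a different receipt date).
* **Missingness knobs** degrade dates to partial precision or blank out
  demographic fields to exercise the precision and missing-policy rules.

Everything is driven by one integer seed; reruns are byte-identical.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .dispro import ContingencyTable
from .faers_io import serialize_icsrs, write_tables
from .records import DrugEntry, FuzzyDate, IcsrRecord


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# mini MedDRA-style dictionary


_SOC_NAMES = [
    "Infections and infestations",
    "Gastrointestinal disorders",
    "Eye disorders",
    "Skin and subcutaneous tissue disorders",
    "Nervous system disorders",
    "General disorders and administration site conditions",
    "Vascular disorders",
    "Immune system disorders",
    "Musculoskeletal and connective tissue disorders",
    "Respiratory, thoracic and mediastinal disorders",
]

_PT_NAMES = [
    "Oral candidiasis", "Oral herpes", "Conjunctivitis", "Eye infection",
    "Colitis ulcerative", "Inflammatory bowel disease", "Diarrhoea", "Nausea",
    "Abdominal discomfort", "Haematochezia", "Pyrexia", "Fatigue", "Headache",
    "Dizziness", "Arthralgia", "Back pain", "Myalgia", "Rash", "Pruritus",
    "Erythema", "Skin exfoliation", "Injection site pain",
    "Injection site erythema", "Nasopharyngitis", "Cough", "Dyspnoea",
    "Hypertension", "Flushing", "Angioedema", "Hypersensitivity",
    "Ocular hyperaemia", "Vision blurred", "Uveitis", "Tonsillitis",
    "Stomatitis", "Vomiting", "Asthenia", "Malaise", "Candida infection",
    "Erysipelas",
]

_SMQ_NAMES = [
    "Ocular infections",
    "Gastrointestinal nonspecific inflammation and dysfunctional conditions",
    "Oropharyngeal infections",
    "Hypersensitivity",
    "Angioedema",
    "Arthritis",
]


def mini_meddra(
    n_socs: int = 8,
    n_pts: int = 40,
    n_smqs: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a small synthetic MedDRA-style dictionary as the two interchange
    tables (PT->SOC with primary flags, and flat SMQ membership).

    Each PT receives exactly one primary SOC; roughly a quarter also get a
    non-primary secondary-SOC row. Each SMQ gets a random PT subset tagged
    narrow or broad at level 1, plus a few level-2 rows so that level
    filtering is exercised. Purely synthetic stand-in for the licensed
    dictionary; names overlap real MedDRA terms only for readability.
    """
    if not (n_pts >= n_socs >= 1):
        raise ConfigurationError("need n_pts >= n_socs >= 1")
    rng = np.random.default_rng(seed)
    socs = [_SOC_NAMES[i % len(_SOC_NAMES)] if i < len(_SOC_NAMES) else f"Synthetic SOC {i:02d}"
            for i in range(n_socs)]
    pts = [_PT_NAMES[i] if i < len(_PT_NAMES) else f"Synthetic event {i:03d}" for i in range(n_pts)]

    pt_rows = []
    for i, pt in enumerate(pts):
        primary = socs[i % n_socs] if i >= n_socs else socs[i]
        pt_rows.append({"pt": pt, "soc": primary, "primary_flag": "true"})
        if rng.random() < 0.25:
            secondary = socs[int(rng.integers(n_socs))]
            if secondary != primary:
                pt_rows.append({"pt": pt, "soc": secondary, "primary_flag": "false"})

    smqs = [_SMQ_NAMES[i % len(_SMQ_NAMES)] if i < len(_SMQ_NAMES) else f"Synthetic SMQ {i:02d}"
            for i in range(n_smqs)]
    smq_rows = []
    for smq in smqs:
        size = int(rng.integers(3, max(4, n_pts // 4)))
        members = rng.choice(n_pts, size=min(size, n_pts), replace=False)
        for j, idx in enumerate(sorted(members)):
            scope = "narrow" if j % 3 != 2 else "broad"
            smq_rows.append({"smq": smq, "level": 1, "scope": scope, "pt": pts[int(idx)]})
        # a couple of level-2 members to exercise the level filter
        extra = rng.choice(n_pts, size=2, replace=False)
        for idx in sorted(extra):
            smq_rows.append({"smq": smq, "level": 2, "scope": "narrow", "pt": pts[int(idx)]})

    return pd.DataFrame(pt_rows), pd.DataFrame(smq_rows)


def write_mini_meddra(out_dir: Union[str, os.PathLike], **kwargs) -> tuple[str, str]:
    """Write the mini dictionary as the two TSVs; returns their paths."""
    os.makedirs(out_dir, exist_ok=True)
    pt_df, smq_df = mini_meddra(**kwargs)
    pt_path = os.path.join(out_dir, "pt_soc.tsv")
    smq_path = os.path.join(out_dir, "smq.tsv")
    pt_df.to_csv(pt_path, sep="\t", index=False)
    smq_df.to_csv(smq_path, sep="\t", index=False)
    return pt_path, smq_path


# ---------------------------------------------------------------------------
# corpus generation


def _default_quarters() -> list[str]:
    return [f"{y}Q{q}" for y in range(2015, 2022) for q in range(1, 5)]


def _default_drug_prevalence() -> dict[str, float]:
    # marginal suspect-drug shares shaped like the study's three-group split
    # (~17% secukinumab, ~56% other biologics, ~26% non-biologics)
    return {
        "secukinumab": 0.175,
        "adalimumab": 0.20,
        "etanercept": 0.10,
        "ustekinumab": 0.08,
        "ixekizumab": 0.05,
        "guselkumab": 0.04,
        "infliximab": 0.03,
        "certolizumab": 0.02,
        "brodalumab": 0.01,
        "risankizumab": 0.02,
        "tildrakizumab": 0.01,
        "methotrexate": 0.13,
        "apremilast": 0.10,
        "acitretin": 0.02,
        "cyclosporine": 0.02,
    }


def _default_indications() -> dict[str, float]:
    return {
        "Psoriasis": 0.85,
        "Guttate psoriasis": 0.04,
        "Pustular psoriasis": 0.04,
        "Nail psoriasis": 0.03,
        "Erythrodermic psoriasis": 0.04,
    }


def _default_event_probs() -> dict[str, float]:
    return {pt: 0.02 for pt in _PT_NAMES}


#: PT appended when a report would otherwise have no reaction (FAERS REAC
#: always carries at least one term); excluded from rankings by default.
FILLER_PT = "Drug ineffective"

_OUTCOME_PROBS = {"DE": 0.021, "LT": 0.02, "HO": 0.147, "DS": 0.013, "CA": 0.0003, "RI": 0.0002, "OT": 0.334}


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic corpus."""

    n_cases: int = 10_000
    quarters: list[str] = field(default_factory=_default_quarters)
    drug_prevalence: dict[str, float] = field(default_factory=_default_drug_prevalence)
    indication_distribution: dict[str, float] = field(default_factory=_default_indications)
    background_event_probs: dict[str, float] = field(default_factory=_default_event_probs)
    injected_associations: list[tuple[str, str, float]] = field(default_factory=list)
    version_dup_rate: float = 0.0
    crosssource_dup_rate: float = 0.0
    missingness: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be >= 1")
        probs = (
            list(self.drug_prevalence.values())
            + list(self.indication_distribution.values())
            + list(self.background_event_probs.values())
            + [self.version_dup_rate, self.crosssource_dup_rate]
            + list(self.missingness.values())
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        for drug, pt, target in self.injected_associations:
            if target <= 0:
                raise ConfigurationError(f"target_ror for ({drug}, {pt}) must be > 0")
            if pt not in self.background_event_probs:
                raise ConfigurationError(f"injected PT {pt!r} has no background probability")
            p1 = tilted_probability(self.background_event_probs[pt], target)
            if not p1 < 1.0:
                raise ConfigurationError(
                    f"derived event probability for ({drug}, {pt}) reaches 1; lower target_ror"
                )


def tilted_probability(background_p: float, target_ror: float) -> float:
    """Exposed-report event probability whose odds are ``target_ror`` times
    the background odds."""
    odds = target_ror * background_p / (1.0 - background_p)
    return odds / (1.0 + odds)


@dataclass
class CaseTruth:
    """Ground truth for one underlying (canonical) case."""

    case_id: str
    suspect_drugs: tuple[str, ...]
    event_pts: tuple[str, ...]
    dedup_key: tuple
    version_primary_ids: tuple[str, ...] = ()
    crosssource_case_ids: tuple[str, ...] = ()


@dataclass
class TruthLedger:
    """Per-case ground truth sufficient to recompute every true 2x2 table
    and the exact expected outcome of both dedup stages."""

    cases: list[CaseTruth]

    @property
    def n_unique_cases(self) -> int:
        return len(self.cases)

    @property
    def n_duplicate_records(self) -> int:
        return sum(
            len(c.version_primary_ids) - 1 + len(c.crosssource_case_ids) for c in self.cases
        )

    def contingency(self, drug: str, pt: str) -> ContingencyTable:
        """True unique-case 2x2 for (suspect drug, event PT): exposed =
        cases with the drug as suspect, comparator = all other cases."""
        a = b = c = d = 0
        for case in self.cases:
            exposed = drug in case.suspect_drugs
            event = pt in case.event_pts
            if exposed and event:
                a += 1
            elif exposed:
                b += 1
            elif event:
                c += 1
            else:
                d += 1
        return ContingencyTable(a, b, c, d, term=pt, level="PT", comparator="all_other_cases")

    def expected_survivors(self) -> int:
        """Number of records the two-stage dedup should leave, applying the
        multifield key semantics (missing matches missing) to the canonical
        cases — distinct cases that are genuinely indistinguishable on the
        key merge by definition."""
        return len({c.dedup_key for c in self.cases})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": [c.case_id for c in self.cases],
                "suspect_drugs": ["|".join(c.suspect_drugs) for c in self.cases],
                "event_pts": ["|".join(c.event_pts) for c in self.cases],
                "n_versions": [len(c.version_primary_ids) for c in self.cases],
                "crosssource_case_ids": ["|".join(c.crosssource_case_ids) for c in self.cases],
            }
        )

    def write(self, out_dir: Union[str, os.PathLike]) -> tuple[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        tsv = os.path.join(out_dir, "truth_ledger.tsv")
        js = os.path.join(out_dir, "truth_ledger.json")
        self.to_frame().to_csv(tsv, sep="\t", index=False)
        with open(js, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "n_unique_cases": self.n_unique_cases,
                    "n_duplicate_records": self.n_duplicate_records,
                    "expected_survivors": self.expected_survivors(),
                    "cases": [
                        {
                            "case_id": c.case_id,
                            "suspect_drugs": list(c.suspect_drugs),
                            "event_pts": list(c.event_pts),
                            "version_primary_ids": list(c.version_primary_ids),
                            "crosssource_case_ids": list(c.crosssource_case_ids),
                        }
                        for c in self.cases
                    ],
                },
                fh,
                indent=1,
            )
        return tsv, js


_COUNTRIES = ["US", "US", "US", "US", "US", "CA", "GB", "DE", "FR", "JP"]


def _quarter_dates(label: str) -> tuple[_dt.date, _dt.date]:
    year, q = int(label[:4]), int(label[-1])
    start = _dt.date(year, 3 * (q - 1) + 1, 1)
    end_month = 3 * q
    last_day = (_dt.date(year + (end_month == 12), (end_month % 12) + 1, 1) - _dt.timedelta(days=1))
    return start, last_day


def _rand_date(rng: np.random.Generator, start: _dt.date, end: _dt.date) -> _dt.date:
    span = (end - start).days
    return start + _dt.timedelta(days=int(rng.integers(0, span + 1)))


def _fuzzy(d: _dt.date) -> FuzzyDate:
    return FuzzyDate(d.year, d.month, d.day)


@dataclass
class GeneratedCorpus:
    records: list[IcsrRecord]
    ledger: TruthLedger
    paths: list[str] = field(default_factory=list)


def generate_corpus(
    config: SimConfig, out_dir: Optional[Union[str, os.PathLike]] = None
) -> GeneratedCorpus:
    """Generate the corpus; optionally write FAERS-dialect quarterly files
    plus the ledger under ``out_dir``. Deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    drugs = sorted(config.drug_prevalence)
    drug_probs = np.array([config.drug_prevalence[d] for d in drugs])
    ind_terms = sorted(config.indication_distribution)
    ind_probs = np.array([config.indication_distribution[t] for t in ind_terms])
    ind_probs = ind_probs / ind_probs.sum()
    event_pts = sorted(config.background_event_probs)
    tilt: dict[str, dict[str, float]] = {}
    for drug, pt, target in config.injected_associations:
        tilt.setdefault(pt, {})[drug] = target
    miss = config.missingness

    records: list[IcsrRecord] = []
    cases: list[CaseTruth] = []
    next_case = 10_000_001
    next_dup_case = 90_000_001

    for i in range(config.n_cases):
        case_id = str(next_case)
        next_case += 1
        quarter = config.quarters[int(rng.integers(len(config.quarters)))]
        qstart, qend = _quarter_dates(quarter)
        fda_date = _rand_date(rng, qstart, qend)
        event_date = fda_date - _dt.timedelta(days=int(rng.integers(0, 120)))

        # suspect drug set: independent draws, at least one guaranteed
        mask = rng.random(len(drugs)) < drug_probs
        suspects = [d for d, m in zip(drugs, mask) if m]
        if not suspects:
            suspects = [drugs[int(rng.choice(len(drugs), p=drug_probs / drug_probs.sum()))]]
        suspects = sorted(suspects)

        # reactions: background odds, tilted for injected exposures
        reactions: list[str] = []
        for pt in event_pts:
            p0 = config.background_event_probs[pt]
            odds = p0 / (1.0 - p0)
            for drug, target in tilt.get(pt, {}).items():
                if drug in suspects:
                    odds *= target  # multiplicative on the odds scale
            p = odds / (1.0 + odds)
            if rng.random() < p:
                reactions.append(pt)
        if not reactions:
            reactions = [FILLER_PT]

        age: Optional[float] = float(int(np.clip(rng.normal(54, 13), 18, 95)))
        age_unit: Optional[str] = "YR"
        u = rng.random()
        sex = "F" if u < 0.565 else ("M" if u < 0.945 else "unknown")
        country: Optional[str] = _COUNTRIES[int(rng.integers(len(_COUNTRIES)))]

        ev: Optional[FuzzyDate] = _fuzzy(event_date)
        if rng.random() < miss.get("event_date", 0.0):
            ev = None
        elif rng.random() < miss.get("event_date_partial", 0.0):
            ev = FuzzyDate(event_date.year, event_date.month)
        if rng.random() < miss.get("age", 0.0):
            age, age_unit = None, None
        if rng.random() < miss.get("sex", 0.0):
            sex = "unknown"
        if rng.random() < miss.get("reporter_country", 0.0):
            country = None

        drug_entries = []
        therapy_starts: dict[int, Optional[FuzzyDate]] = {}
        for seq, name in enumerate(suspects, start=1):
            term = ind_terms[int(rng.choice(len(ind_terms), p=ind_probs))]
            drug_entries.append(
                DrugEntry(
                    drug_seq=seq,
                    role="PS" if seq == 1 else "SS",
                    raw_name=name.upper(),
                    active_ingredient=name,
                    indications={term},
                )
            )
            onset = int(np.clip(rng.lognormal(np.log(92), 1.1), 0, 2000))
            therapy_starts[seq] = _fuzzy(event_date - _dt.timedelta(days=onset))
        if rng.random() < 0.3:  # concomitant out-of-catalog noise drug
            drug_entries.append(
                DrugEntry(
                    drug_seq=len(drug_entries) + 1,
                    role="C",
                    raw_name=["ASPIRIN", "IBUPROFEN", "OMEPRAZOLE", "LISINOPRIL"][int(rng.integers(4))],
                )
            )

        outcomes = {code for code, p in _OUTCOME_PROBS.items() if rng.random() < p}
        rt = rng.random()
        report_type = "direct" if rt < 0.08 else ("expedited" if rt < 0.48 else "non-expedited")
        oc = rng.random()
        occupation = (
            "consumer" if oc < 0.55 else
            "physician" if oc < 0.72 else
            "pharmacist" if oc < 0.78 else "other"
        )

        base = IcsrRecord(
            primary_id=f"{case_id}1",
            case_id=case_id,
            case_version=1,
            event_date=ev,
            fda_receipt_date=_fuzzy(fda_date),
            age_value=age,
            age_unit=age_unit,
            sex=sex,
            reporter_country=country,
            report_type=report_type,
            reporter_occupation=occupation,
            drugs=drug_entries,
            reactions=set(reactions),
            outcomes=outcomes,
            therapy_starts=therapy_starts,
        )
        records.append(base)

        version_ids = [base.primary_id]
        if rng.random() < config.version_dup_rate:
            n_extra = int(rng.integers(1, 4))
            for v in range(2, 2 + n_extra):
                rec = _clone(base, primary_id=f"{case_id}{v}", case_version=v)
                rec.fda_receipt_date = _fuzzy(
                    min(fda_date + _dt.timedelta(days=int(rng.integers(1, 60))), qend)
                )
                records.append(rec)
                version_ids.append(rec.primary_id)

        cross_ids = []
        if rng.random() < config.crosssource_dup_rate:
            dup_case = str(next_dup_case)
            next_dup_case += 1
            rec = _clone(base, primary_id=f"{dup_case}1", case_id=dup_case, case_version=1)
            rec.fda_receipt_date = _fuzzy(
                min(fda_date + _dt.timedelta(days=int(rng.integers(1, 90))), qend)
            )
            rec.report_type = "expedited" if base.report_type != "expedited" else "non-expedited"
            records.append(rec)
            cross_ids.append(dup_case)

        key = (
            (ev.year, ev.month, ev.day) if ev else None,
            (age, age_unit) if age is not None else None,
            sex,
            country.casefold() if country else None,
            tuple(suspects),
            tuple(sorted(r.casefold() for r in reactions)),
        )
        cases.append(
            CaseTruth(
                case_id=case_id,
                suspect_drugs=tuple(suspects),
                event_pts=tuple(sorted(reactions)),
                dedup_key=key,
                version_primary_ids=tuple(version_ids),
                crosssource_case_ids=tuple(cross_ids),
            )
        )

    ledger = TruthLedger(cases)
    corpus = GeneratedCorpus(records=records, ledger=ledger)
    if out_dir is not None:
        by_quarter: dict[str, list[IcsrRecord]] = {}
        for rec in records:
            label = f"{rec.fda_receipt_date.year}Q{(rec.fda_receipt_date.month - 1) // 3 + 1}"
            by_quarter.setdefault(label, []).append(rec)
        for label in sorted(by_quarter):
            tables = serialize_icsrs(by_quarter[label], quarter_label=label)
            corpus.paths.extend(write_tables(tables, out_dir, label))
        ledger.write(out_dir)
    return corpus


def _clone(base: IcsrRecord, **overrides) -> IcsrRecord:
    rec = IcsrRecord(
        primary_id=base.primary_id,
        case_id=base.case_id,
        case_version=base.case_version,
        event_date=base.event_date,
        fda_receipt_date=base.fda_receipt_date,
        age_value=base.age_value,
        age_unit=base.age_unit,
        sex=base.sex,
        reporter_country=base.reporter_country,
        report_type=base.report_type,
        reporter_occupation=base.reporter_occupation,
        drugs=[
            DrugEntry(d.drug_seq, d.role, d.raw_name, d.active_ingredient, set(d.indications))
            for d in base.drugs
        ],
        reactions=set(base.reactions),
        outcomes=set(base.outcomes),
        therapy_starts=dict(base.therapy_starts),
        report_sources=set(base.report_sources),
    )
    for key, value in overrides.items():
        setattr(rec, key, value)
    return rec


# ---------------------------------------------------------------------------
# direct association sampling (for calibration studies)


def sample_association_table(
    n_exposed: int,
    n_comparator: int,
    background_p: float,
    target_ror: float,
    rng: Union[int, np.random.Generator],
) -> ContingencyTable:
    """Draw one 2x2 table under the designed association structure: the
    comparator group reports the event with the background probability, the
    exposed group with odds tilted by ``target_ror``. This is the sampling
    model the corpus generator uses for injected pairs, without the
    file-format overhead — the tool for coverage/calibration studies."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    p1 = tilted_probability(background_p, target_ror)
    a = int(rng.binomial(n_exposed, p1))
    c = int(rng.binomial(n_comparator, background_p))
    return ContingencyTable(a, n_exposed - a, c, n_comparator - c)
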