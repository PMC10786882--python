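"""Psoriasis cohort construction and exposure-group assignment.

The study design selects reports whose *suspect* (primary or secondary
suspect role) medications are systemic psoriasis therapies and carry a
psoriasis indication, then splits them into three exposure groups:

1. secukinumab reports (regardless of other anti-psoriatic suspects),
2. reports with any other biologic of interest as a suspect,
3. reports with a non-biologic agent as a suspect.

Group 1 takes precedence and is exclusive; groups 2 and 3 may overlap (one
report can suspect both a biologic and a non-biologic), so comparator group
sizes can sum to more than the record count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import yaml

from .records import IcsrRecord

#: The five indication preferred terms defining the psoriasis cohort.
DEFAULT_INDICATION_TERMS = frozenset(
    {
        "psoriasis",
        "guttate psoriasis",
        "pustular psoriasis",
        "nail psoriasis",
        "erythrodermic psoriasis",
    }
)

BIOLOGICS = frozenset(
    {
        "adalimumab",
        "brodalumab",
        "certolizumab",
        "etanercept",
        "guselkumab",
        "infliximab",
        "ixekizumab",
        "risankizumab",
        "secukinumab",
        "tildrakizumab",
        "ustekinumab",
    }
)

NON_BIOLOGICS = frozenset({"acitretin", "apremilast", "cyclosporine", "methotrexate"})

#: US brand names and common variants for the catalog drugs. FAERS drugname
#: is free text, so matching is by token containment after normalization.
DEFAULT_SYNONYMS = {
    "humira": "adalimumab",
    "siliq": "brodalumab",
    "cimzia": "certolizumab",
    "certolizumab pegol": "certolizumab",
    "enbrel": "etanercept",
    "tremfya": "guselkumab",
    "remicade": "infliximab",
    "taltz": "ixekizumab",
    "skyrizi": "risankizumab",
    "cosentyx": "secukinumab",
    "ilumya": "tildrakizumab",
    "stelara": "ustekinumab",
    "soriatane": "acitretin",
    "otezla": "apremilast",
    "neoral": "cyclosporine",
    "sandimmune": "cyclosporine",
    "gengraf": "cyclosporine",
    "ciclosporin": "cyclosporine",
    "cyclosporin": "cyclosporine",
    "trexall": "methotrexate",
    "rheumatrex": "methotrexate",
    "otrexup": "methotrexate",
    "rasuvo": "methotrexate",
    "methotrexate sodium": "methotrexate",
}


class ConfigurationError(ValueError):
    pass


@dataclass
class DrugCatalog:
    """The study's drug lists plus a raw-name -> canonical synonym table."""

    biologics: frozenset[str] = BIOLOGICS
    non_biologics: frozenset[str] = NON_BIOLOGICS
    synonyms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SYNONYMS))

    def __post_init__(self) -> None:
        overlap = set(self.biologics) & set(self.non_biologics)
        if overlap:
            raise ConfigurationError(f"drugs listed as both biologic and non-biologic: {overlap}")
        all_drugs = set(self.biologics) | set(self.non_biologics)
        bad = {v for v in self.synonyms.values() if v not in all_drugs}
        if bad:
            raise ConfigurationError(f"synonym targets outside the catalog: {bad}")

    @property
    def all_drugs(self) -> frozenset[str]:
        return frozenset(self.biologics) | frozenset(self.non_biologics)

    @classmethod
    def from_yaml(cls, path: str) -> "DrugCatalog":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            biologics=frozenset(data.get("biologics", BIOLOGICS)),
            non_biologics=frozenset(data.get("non_biologics", NON_BIOLOGICS)),
            synonyms={**DEFAULT_SYNONYMS, **{k.casefold(): v for k, v in data.get("synonyms", {}).items()}},
        )


_PUNCT = re.compile(r"[^a-z0-9]+")


def _normalize_text(raw: str) -> str:
    return " " + _PUNCT.sub(" ", raw.casefold()).strip() + " "


def normalize_drug_name(raw: Optional[str], catalog: DrugCatalog) -> Optional[str]:
    """Map a free-text drug name (or active-ingredient string) to a catalog
    canonical name, or None when out of catalog.

    Matching is case-insensitive and punctuation-tolerant; a canonical name
    or synonym appearing as a whole token (or token phrase) inside the raw
    string qualifies, so salt forms like "Methotrexate Sodium" resolve to
    methotrexate and brand names resolve via the synonym table.
    """
    if raw is None or not raw.strip():
        return None
    text = _normalize_text(raw)
    # longest patterns first so multi-word synonyms win over fragments
    candidates = sorted(
        [(name, name) for name in catalog.all_drugs]
        + list(catalog.synonyms.items()),
        key=lambda item: -len(item[0]),
    )
    for pattern, canonical in candidates:
        norm_pattern = _normalize_text(pattern).strip()
        if norm_pattern and f" {norm_pattern} " in text:
            return canonical
    return None


def canonical_suspects(record: IcsrRecord, catalog: DrugCatalog) -> set[str]:
    """Canonical catalog names among a record's suspect-role drugs (name or
    active-ingredient match)."""
    out = set()
    for drug in record.suspect_drugs():
        name = normalize_drug_name(drug.raw_name, catalog) or normalize_drug_name(
            drug.active_ingredient, catalog
        )
        if name is not None:
            out.add(name)
    return out


def filter_psoriasis_reports(
    records: Iterable[IcsrRecord],
    indication_terms: Iterable[str] = DEFAULT_INDICATION_TERMS,
    catalog: Optional[DrugCatalog] = None,
    strict: bool = True,
) -> list[IcsrRecord]:
    """Keep reports where a suspect catalog drug is indicated for psoriasis.

    Strict mode (default) requires the indication term on the qualifying
    suspect drug itself (the INDI table links indications to drug sequence
    numbers). Lenient mode accepts a matching indication anywhere in the
    report as long as some suspect drug is in the catalog. Indication
    matching is exact PT match, case-insensitive — substring matching would
    wrongly catch terms like "psoriatic arthropathy".

    Qualifying canonical drug names are marked on each kept record
    (``record.qualifying_drugs``).
    """
    catalog = catalog or DrugCatalog()
    terms = {t.strip().casefold() for t in indication_terms if t.strip()}
    if not terms:
        raise ConfigurationError("indication_terms must be non-empty")

    kept: list[IcsrRecord] = []
    for rec in records:
        qualifying: set[str] = set()
        report_has_term = any(
            ind.strip().casefold() in terms for d in rec.drugs for ind in d.indications
        )
        for drug in rec.suspect_drugs():
            name = normalize_drug_name(drug.raw_name, catalog) or normalize_drug_name(
                drug.active_ingredient, catalog
            )
            if name is None:
                continue
            drug_has_term = any(ind.strip().casefold() in terms for ind in drug.indications)
            if drug_has_term or (not strict and report_has_term):
                qualifying.add(name)
        if qualifying:
            rec.qualifying_drugs = qualifying
            kept.append(rec)
    return kept


@dataclass(frozen=True)
class CohortAssignment:
    primary_id: str
    in_secukinumab: bool
    in_other_biologics: bool
    in_non_biologics: bool


class CohortInvariantError(RuntimeError):
    """A record reached group assignment without any qualifying suspect
    catalog drug (should have been removed by the psoriasis filter)."""


def assign_groups(
    records: Iterable[IcsrRecord], catalog: Optional[DrugCatalog] = None
) -> list[CohortAssignment]:
    """Assign each filtered record to exposure groups.

    Secukinumab membership is exclusive and takes precedence; otherwise a
    record joins the other-biologics and/or non-biologics comparator groups
    according to its suspect catalog drugs (possibly both).
    """
    catalog = catalog or DrugCatalog()
    out = []
    for rec in records:
        suspects = rec.qualifying_drugs or canonical_suspects(rec, catalog)
        if not suspects:
            raise CohortInvariantError(f"record {rec.primary_id} has no qualifying suspect drug")
        if "secukinumab" in suspects:
            out.append(CohortAssignment(rec.primary_id, True, False, False))
            continue
        other_bio = bool(suspects & (set(catalog.biologics) - {"secukinumab"}))
        non_bio = bool(suspects & set(catalog.non_biologics))
        out.append(CohortAssignment(rec.primary_id, False, other_bio, non_bio))
    return out


def split_groups(
    records: list[IcsrRecord], assignments: list[CohortAssignment]
) -> dict[str, list[IcsrRecord]]:
    """Materialize the three record groups from assignments."""
    by_id = {a.primary_id: a for a in assignments}
    groups: dict[str, list[IcsrRecord]] = {"secukinumab": [], "other_biologics": [], "non_biologics": []}
    for rec in records:
        a = by_id.get(rec.primary_id)
        if a is None:
            continue
        if a.in_secukinumab:
            groups["secukinumab"].append(rec)
        if a.in_other_biologics:
            groups["other_biologics"].append(rec)
        if a.in_non_biologics:
            groups["non_biologics"].append(rec)
    return groups
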