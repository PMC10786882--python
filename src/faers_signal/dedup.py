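"""Two-stage deduplication of spontaneous reports.

Stage 1 (*case-version dedup*): a case revised over time appears once per
version under the same case id; only the latest version is retained.

Stage 2 (*multifield dedup*): the same event reported through different
sources receives different case ids; records matching on event date, age,
sex, reporter country, suspect drugs, and reaction terms are collapsed to a
single representative. Within a duplicate cluster the record with the
latest FDA receipt date survives (latest report is the most complete and
corrected), ties broken by smallest primary id.

Suspect drugs in the key are the catalog-canonicalized names of
primary/secondary-suspect drugs (brand and generic forms of the same drug
should match), falling back to case-folded raw names out of catalog.
Missing key fields compare equal under the default ``missing_matches``
policy; under ``missing_never_matches`` a record with any missing key field
is never collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .cohort import DrugCatalog, normalize_drug_name
from .records import IcsrRecord

MISSING_POLICIES = ("missing_matches", "missing_never_matches")


@dataclass(frozen=True)
class DedupKey:
    """The multifield matching key. Tuple fields are sorted, case-folded
    and duplicate-free so the key is order-insensitive."""

    event_date: Optional[tuple]
    age: Optional[tuple]
    sex: str
    reporter_country: Optional[str]
    suspect_drugs: tuple[str, ...]
    reaction_terms: tuple[str, ...]

    def has_missing(self) -> bool:
        return (
            self.event_date is None
            or self.age is None
            or self.sex == "unknown"
            or self.reporter_country is None
            or not self.suspect_drugs
            or not self.reaction_terms
        )


def build_dedup_key(record: IcsrRecord, catalog: Optional[DrugCatalog] = None) -> DedupKey:
    drugs = set()
    for d in record.suspect_drugs():
        name = None
        if catalog is not None:
            name = normalize_drug_name(d.raw_name, catalog) or normalize_drug_name(
                d.active_ingredient, catalog
            )
        drugs.add(name if name is not None else d.raw_name.strip().casefold())
    # age compared as reported (value, unit): unit conversion would merge
    # reports that are not literally identical
    age = (record.age_value, record.age_unit) if record.age_value is not None else None
    return DedupKey(
        event_date=(record.event_date.year, record.event_date.month, record.event_date.day)
        if record.event_date
        else None,
        age=age,
        sex=record.sex,
        reporter_country=record.reporter_country.strip().casefold()
        if record.reporter_country
        else None,
        suspect_drugs=tuple(sorted(drugs)),
        reaction_terms=tuple(sorted({r.strip().casefold() for r in record.reactions})),
    )


@dataclass
class AuditEntry:
    removed_primary_id: str
    survivor_primary_id: str
    stage: str  # "version" or "multifield"


@dataclass
class DedupResult:
    records: list[IcsrRecord]
    removed: list[AuditEntry] = field(default_factory=list)

    @property
    def removed_count(self) -> int:
        return len(self.removed)


def _receipt_sort_key(rec: IcsrRecord) -> tuple:
    date_key = rec.fda_receipt_date.sort_key() if rec.fda_receipt_date else (0, 0, 0)
    # later receipt wins; ties -> lexicographically smallest primary id wins,
    # so invert the id ordering via sorted() picking max on the tuple
    return date_key


def keep_latest_version(records: Iterable[IcsrRecord]) -> DedupResult:
    """Retain exactly one record per case id: the maximal case version.

    Version ties (which violate the FAERS contract but are tolerated) break
    by latest FDA receipt date, then smallest primary id.
    """
    by_case: dict[str, list[IcsrRecord]] = {}
    for rec in records:
        by_case.setdefault(rec.case_id, []).append(rec)

    kept: list[IcsrRecord] = []
    removed: list[AuditEntry] = []
    for case_id in sorted(by_case):
        group = by_case[case_id]
        winner = max(
            group,
            key=lambda r: (r.case_version, _receipt_sort_key(r), _InvertedStr(r.primary_id)),
        )
        kept.append(winner)
        for rec in group:
            if rec is not winner:
                removed.append(AuditEntry(rec.primary_id, winner.primary_id, "version"))
    kept.sort(key=lambda r: r.primary_id)
    return DedupResult(kept, removed)


class _InvertedStr(str):
    """Orders strings in reverse, so max() prefers the *smallest* id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def multifield_dedup(
    records: Iterable[IcsrRecord],
    missing_policy: str = "missing_matches",
    catalog: Optional[DrugCatalog] = None,
) -> DedupResult:
    """Collapse cross-source duplicates sharing an identical multifield key.

    Input must already be case-version deduplicated. The survivor of each
    cluster is the record with the latest FDA receipt date, ties broken by
    smallest primary id.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")

    clusters: dict[DedupKey, list[IcsrRecord]] = {}
    passthrough: list[IcsrRecord] = []
    for rec in records:
        key = build_dedup_key(rec, catalog)
        if missing_policy == "missing_never_matches" and key.has_missing():
            passthrough.append(rec)
            continue
        clusters.setdefault(key, []).append(rec)

    kept: list[IcsrRecord] = list(passthrough)
    removed: list[AuditEntry] = []
    for key in clusters:
        group = clusters[key]
        winner = max(group, key=lambda r: (_receipt_sort_key(r), _InvertedStr(r.primary_id)))
        kept.append(winner)
        for rec in group:
            if rec is not winner:
                removed.append(AuditEntry(rec.primary_id, winner.primary_id, "multifield"))
    kept.sort(key=lambda r: r.primary_id)
    removed.sort(key=lambda e: e.removed_primary_id)
    return DedupResult(kept, removed)


def deduplicate(
    records: Iterable[IcsrRecord],
    missing_policy: str = "missing_matches",
    catalog: Optional[DrugCatalog] = None,
) -> tuple[DedupResult, DedupResult]:
    """Run both stages in the study's order: version dedup strictly first."""
    stage1 = keep_latest_version(records)
    stage2 = multifield_dedup(stage1.records, missing_policy=missing_policy, catalog=catalog)
    return stage1, stage2
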