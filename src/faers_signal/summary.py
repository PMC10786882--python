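"""Descriptive summaries of a report group: demographics, outcomes,
reporting channels, yearly counts, onset latency, and most-common-term
rankings.

Continuous variables are reported as median (IQR) using the inclusive
linear-interpolation quantile convention (the common spreadsheet /
statistics default; the numbers depend on this choice, so it is pinned).
Age statistics use only reports whose age is recorded in years — FAERS
ages arrive in years, decades, months, or days and the other units are
excluded rather than converted. A report with several serious-outcome
codes contributes once to each outcome tally, so outcome counts may sum to
more than the group size.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import numpy as np

from .cohort import DrugCatalog, normalize_drug_name
from .meddra import MeddraDictionary
from .records import OUTCOME_CODES, IcsrRecord

_CATALOG = DrugCatalog()


class ConfigurationError(ValueError):
    pass


def format_percentage(count: float, n: float, decimals: int = 2) -> str:
    """``100*count/n`` rounded half-up to ``decimals`` places, as printed in
    tabular reports. Recomputable from its numerator and denominator."""
    if n == 0:
        return ""
    pct = Decimal(100 * count) / Decimal(n)
    quantum = Decimal(1).scaleb(-decimals)
    return str(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def percentage_value(count: float, n: float, decimals: int = 2) -> float:
    return float(format_percentage(count, n, decimals)) if n else float("nan")


def _median_iqr(values: list[float]) -> tuple[Optional[float], Optional[float], Optional[float]]:
    if not values:
        return None, None, None
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q1), float(q3)


@dataclass
class MedianIqr:
    median: Optional[float]
    iqr_low: Optional[float]
    iqr_high: Optional[float]
    n: int


@dataclass
class GroupSummary:
    n: int
    age_overall: MedianIqr
    age_by_sex: dict[str, MedianIqr]
    sex_counts: dict[str, int]
    outcome_counts: dict[str, int]
    report_type_counts: dict[str, int]
    reporter_occupation_counts: dict[str, int]
    yearly_counts: dict[int, int]
    onset_days: MedianIqr
    negative_onset_count: int = 0
    decimals: int = 2

    def sex_percentages(self) -> dict[str, float]:
        return {k: percentage_value(v, self.n, self.decimals) for k, v in self.sex_counts.items()}

    def outcome_percentages(self) -> dict[str, float]:
        return {k: percentage_value(v, self.n, self.decimals) for k, v in self.outcome_counts.items()}

    def report_type_percentages(self) -> dict[str, float]:
        return {k: percentage_value(v, self.n, self.decimals) for k, v in self.report_type_counts.items()}

    def reporter_occupation_percentages(self) -> dict[str, float]:
        return {
            k: percentage_value(v, self.n, self.decimals)
            for k, v in self.reporter_occupation_counts.items()
        }

    def yearly_percentages(self) -> dict[int, float]:
        return {k: percentage_value(v, self.n, self.decimals) for k, v in self.yearly_counts.items()}


def _onset_days(rec: IcsrRecord, target_drug: str) -> Optional[int]:
    """Days from earliest day-precision therapy start of the target drug to
    the (day-precision) event date; None when either side lacks precision."""
    if rec.event_date is None or rec.event_date.to_date() is None:
        return None
    starts = []
    for drug in rec.drugs:
        name = normalize_drug_name(drug.raw_name, _CATALOG) or normalize_drug_name(
            drug.active_ingredient, _CATALOG
        )
        if name != target_drug:
            continue
        start = rec.therapy_starts.get(drug.drug_seq)
        if start is not None and start.to_date() is not None:
            starts.append(start.to_date())
    if not starts:
        return None
    return (rec.event_date.to_date() - min(starts)).days


def summarize_group(
    records: Iterable[IcsrRecord],
    target_drug: Optional[str] = None,
    decimals: int = 2,
) -> GroupSummary:
    """Build the descriptive summary of one report group.

    ``target_drug`` (canonical name) drives onset-latency computation:
    latency is event date minus the earliest therapy start among the
    drug's entries, requiring day precision on both sides; negative
    latencies are excluded and tallied rather than silently included.
    """
    records = list(records)
    n = len(records)

    ages_all: list[float] = []
    ages_by_sex: dict[str, list[float]] = {"F": [], "M": [], "unknown": []}
    sex_counts = {"F": 0, "M": 0, "unknown": 0}
    outcome_counts = {code: 0 for code in OUTCOME_CODES}
    report_type_counts = {"direct": 0, "expedited": 0, "non-expedited": 0, "unknown": 0}
    occupation_counts = {"consumer": 0, "physician": 0, "pharmacist": 0, "other": 0, "unknown": 0}
    yearly_counts: dict[int, int] = {}
    onsets: list[float] = []
    negative_onsets = 0

    for rec in records:
        sex_counts[rec.sex] = sex_counts.get(rec.sex, 0) + 1
        age = rec.age_in_years
        if age is not None:
            ages_all.append(age)
            ages_by_sex.setdefault(rec.sex, []).append(age)
        for code in rec.outcomes:
            if code in outcome_counts:
                outcome_counts[code] += 1
        report_type_counts[rec.report_type] = report_type_counts.get(rec.report_type, 0) + 1
        occupation_counts[rec.reporter_occupation] = (
            occupation_counts.get(rec.reporter_occupation, 0) + 1
        )
        if rec.fda_receipt_date is not None:
            yearly_counts[rec.fda_receipt_date.year] = (
                yearly_counts.get(rec.fda_receipt_date.year, 0) + 1
            )
        if target_drug is not None:
            onset = _onset_days(rec, target_drug)
            if onset is not None:
                if onset >= 0:
                    onsets.append(onset)
                else:
                    negative_onsets += 1

    return GroupSummary(
        n=n,
        age_overall=MedianIqr(*_median_iqr(ages_all), n=len(ages_all)),
        age_by_sex={
            sex: MedianIqr(*_median_iqr(vals), n=len(vals)) for sex, vals in ages_by_sex.items()
        },
        sex_counts=sex_counts,
        outcome_counts=outcome_counts,
        report_type_counts=report_type_counts,
        reporter_occupation_counts=occupation_counts,
        yearly_counts=dict(sorted(yearly_counts.items())),
        onset_days=MedianIqr(*_median_iqr(onsets), n=len(onsets)),
        negative_onset_count=negative_onsets,
        decimals=decimals,
    )


def rank_common_terms(
    records: Iterable[IcsrRecord],
    dictionary: Optional[MeddraDictionary] = None,
    level: str = "PT",
    exclusions: Iterable[str] = (),
    top_k: int = 10,
) -> list[tuple[str, float]]:
    """Most common event terms at the PT / SOC / SMQ level, as (term,
    percentage of reports containing it), descending, ties by term text.

    ``exclusions`` removes terms before ranking — e.g. indication-echo
    terms like the treated disease itself, which would otherwise dominate.
    """
    if top_k <= 0:
        raise ConfigurationError("top_k must be positive")
    records = list(records)
    n = len(records)
    if n == 0:
        return []
    excluded = {e.strip().casefold() for e in exclusions}

    counts: dict[str, int] = {}
    if level == "PT":
        for rec in records:
            for pt in {p.strip() for p in rec.reactions}:
                counts[pt] = counts.get(pt, 0) + 1
    elif level == "SOC":
        if dictionary is None:
            raise ConfigurationError("SOC-level ranking needs a dictionary")
        for rec in records:
            socs = {dictionary.soc_of(pt) for pt in rec.reactions}
            for soc in socs - {None}:
                counts[soc] = counts.get(soc, 0) + 1
    elif level == "SMQ":
        if dictionary is None:
            raise ConfigurationError("SMQ-level ranking needs a dictionary")
        smq_pts = {
            smq: {p.casefold() for p in dictionary.pts_for_smq(smq, scope="narrow", level=1)}
            for smq in dictionary.smq_names()
        }
        for rec in records:
            rec_pts = {p.strip().casefold() for p in rec.reactions}
            for smq, pts in smq_pts.items():
                if rec_pts & pts:
                    counts[smq] = counts.get(smq, 0) + 1
    else:
        raise ConfigurationError(f"unknown level {level!r}")

    ranked = [
        (term, 100.0 * cnt / n)
        for term, cnt in counts.items()
        if term.strip().casefold() not in excluded
    ]
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return ranked[:top_k]
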