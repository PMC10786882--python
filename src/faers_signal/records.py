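"""Core record types for individual case safety reports (ICSRs).

An ICSR is one adverse-event report in a spontaneous reporting database.
FAERS distributes each quarter as seven dollar-delimited tables keyed by a
*primary id* — the concatenation of a case id and a case version number —
and the types here hold the consolidated per-report view after joining
those tables.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

#: FAERS drug role codes -> semantic role names.
ROLE_CODES = {
    "PS": "primary_suspect",
    "SS": "secondary_suspect",
    "C": "concomitant",
    "I": "interacting",
}

SUSPECT_ROLES = frozenset({"PS", "SS"})

#: Serious-outcome codes from the OUTC table: death, life-threatening,
#: hospitalization (initial or prolonged), disability, congenital anomaly,
#: required intervention, other serious.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: DEMO report-type codes -> channel. EXP = manufacturer 15-day expedited,
#: PER = manufacturer periodic (non-expedited), DIR = public direct report.
REPORT_TYPE_CODES = {"EXP": "expedited", "PER": "non-expedited", "DIR": "direct"}
REPORT_TYPE_TO_CODE = {v: k for k, v in REPORT_TYPE_CODES.items()}

#: DEMO reporter-occupation codes. CN = consumer, MD = physician,
#: PH = pharmacist; lawyers and other health professionals fold into "other".
OCCUPATION_CODES = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other",
    "LW": "other",
    "HP": "other",
}

AGE_UNIT_CODES = {
    "YR": "years",
    "DEC": "decades",
    "MON": "months",
    "WK": "weeks",
    "DY": "days",
    "HR": "hours",
}


@dataclass(frozen=True)
class FuzzyDate:
    """A calendar date of possibly reduced precision.

    FAERS date fields are YYYYMMDD but partial dates (YYYY or YYYYMM) occur;
    these are retained at reduced precision rather than discarded.
    Comparisons that require day precision treat partial dates as missing.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    @classmethod
    def parse(cls, text: str) -> Optional["FuzzyDate"]:
        """Parse YYYYMMDD / YYYYMM / YYYY; anything unparseable -> None."""
        text = text.strip()
        if not text.isdigit():
            return None
        try:
            if len(text) == 8:
                d = _dt.date(int(text[:4]), int(text[4:6]), int(text[6:8]))
                return cls(d.year, d.month, d.day)
            if len(text) == 6:
                year, month = int(text[:4]), int(text[4:6])
                if not 1 <= month <= 12:
                    return None
                return cls(year, month)
            if len(text) == 4:
                return cls(int(text))
        except ValueError:
            return None
        return None

    def to_date(self) -> Optional[_dt.date]:
        """Exact date if day precision, else None."""
        if self.precision != "day":
            return None
        return _dt.date(self.year, self.month, self.day)

    def faers_str(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"

    def sort_key(self) -> tuple:
        return (self.year, self.month or 0, self.day or 0)


@dataclass
class DrugEntry:
    """One DRUG-table row attached to a report, with its INDI indications."""

    drug_seq: int
    role: str  # one of ROLE_CODES keys: PS, SS, C, I
    raw_name: str
    active_ingredient: Optional[str] = None
    indications: set[str] = field(default_factory=set)

    @property
    def is_suspect(self) -> bool:
        return self.role in SUSPECT_ROLES


@dataclass
class IcsrRecord:
    """One consolidated safety report joined across the seven FAERS tables."""

    primary_id: str
    case_id: str
    case_version: int
    event_date: Optional[FuzzyDate] = None
    fda_receipt_date: Optional[FuzzyDate] = None
    age_value: Optional[float] = None
    age_unit: Optional[str] = None  # raw FAERS code (YR, DEC, MON, WK, DY, HR)
    sex: str = "unknown"  # F / M / unknown
    reporter_country: Optional[str] = None
    report_type: str = "unknown"  # direct / expedited / non-expedited / unknown
    reporter_occupation: str = "unknown"
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: set[str] = field(default_factory=set)
    outcomes: set[str] = field(default_factory=set)
    therapy_starts: dict[int, Optional[FuzzyDate]] = field(default_factory=dict)
    report_sources: set[str] = field(default_factory=set)
    #: canonical names of suspect catalog drugs that carried a qualifying
    #: indication; populated by the cohort filter.
    qualifying_drugs: set[str] = field(default_factory=set)

    def suspect_drugs(self) -> list[DrugEntry]:
        return [d for d in self.drugs if d.is_suspect]

    @property
    def age_in_years(self) -> Optional[float]:
        """Age when reported in years; other units are not converted."""
        if self.age_value is not None and self.age_unit == "YR":
            return self.age_value
        return None
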