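"""Case/non-case disproportionality statistics: PRR and ROR with 95% CIs.

For one event-term set and one comparator group, the 2x2 report-count
table is::

                        event of interest   all other events
    medication of interest       A                  B
    comparator medications       C                  D

* PRR (proportional reporting ratio) = (A/(A+B)) / (C/(C+D)), with the
  log-normal CI  exp(ln PRR +/- 1.96 * sqrt(1/A - 1/(A+B) + 1/C - 1/(C+D))).
* ROR (reporting odds ratio) = (A/B)/(C/D) = AD/BC, with the Woolf
  log-normal CI  exp(ln ROR +/- 1.96 * sqrt(1/A + 1/B + 1/C + 1/D)).

A drug-event pair is flagged as a *signal* when PRR > 2 and ROR > 2 and
the ROR 95% CI lower bound > 1 (strict inequalities). Signals are
hypothesis-generating, not causal.

Zero cells make one or both statistics undefined; the default policy
reports them as undefined with a flag (never silently fabricating a
signal). The optional ``halves`` continuity policy adds 0.5 to all four
cells whenever any cell is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .meddra import MeddraDictionary
from .records import IcsrRecord

Z_95 = 1.96

LEVELS = ("SOC", "SMQ", "PT")
CONTINUITY_POLICIES = ("none", "halves")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    a: float
    b: float
    c: float
    d: float
    term: str = ""
    level: str = "PT"
    comparator: str = ""

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b <= 0 or self.c + self.d <= 0:
            raise ValueError("both group sizes must be positive")

    @property
    def exposed_total(self) -> float:
        return self.a + self.b

    @property
    def comparator_total(self) -> float:
        return self.c + self.d


@dataclass(frozen=True)
class RatioEstimate:
    point: float
    ci_low: float
    ci_high: float
    defined: bool = True


@dataclass(frozen=True)
class DisproResult:
    table: ContingencyTable
    prr: float
    prr_ci_low: float
    prr_ci_high: float
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    is_signal: bool
    continuity_corrected: bool
    defined: bool


def _maybe_correct(t: ContingencyTable, continuity: str) -> tuple[ContingencyTable, bool]:
    if continuity not in CONTINUITY_POLICIES:
        raise ConfigurationError(f"continuity must be one of {CONTINUITY_POLICIES}")
    if continuity == "halves" and min(t.a, t.b, t.c, t.d) == 0:
        return (
            ContingencyTable(t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5, t.term, t.level, t.comparator),
            True,
        )
    return t, False


def prr(t: ContingencyTable, continuity: str = "none") -> RatioEstimate:
    """Proportional reporting ratio with its log-normal 95% CI.

    ``a == 0`` yields point 0 with an undefined CI; ``c == 0`` (comparator
    never reports the event) leaves the statistic undefined. Both are
    flagged rather than raised.
    """
    t, _ = _maybe_correct(t, continuity)
    if t.c == 0:
        return RatioEstimate(math.nan, math.nan, math.nan, defined=False)
    if t.a == 0:
        return RatioEstimate(0.0, math.nan, math.nan, defined=False)
    point = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se = math.sqrt(1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d))
    return RatioEstimate(
        point, math.exp(math.log(point) - Z_95 * se), math.exp(math.log(point) + Z_95 * se)
    )


def ror(t: ContingencyTable, continuity: str = "none") -> RatioEstimate:
    """Reporting odds ratio AD/BC with its Woolf log-normal 95% CI."""
    t, _ = _maybe_correct(t, continuity)
    if t.b == 0 or t.c == 0:
        return RatioEstimate(math.nan, math.nan, math.nan, defined=False)
    if t.a == 0 or t.d == 0:
        point = 0.0 if t.a == 0 else math.inf
        return RatioEstimate(point, math.nan, math.nan, defined=False)
    point = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return RatioEstimate(
        point, math.exp(math.log(point) - Z_95 * se), math.exp(math.log(point) + Z_95 * se)
    )


def classify_signal(prr_est: RatioEstimate, ror_est: RatioEstimate) -> bool:
    """Signal verdict: PRR > 2 and ROR > 2 and ROR CI lower bound > 1,
    strict inequalities; undefined statistics are never signals."""
    if not (prr_est.defined and ror_est.defined):
        return False
    return prr_est.point > 2 and ror_est.point > 2 and ror_est.ci_low > 1


def disproportionality(t: ContingencyTable, continuity: str = "none") -> DisproResult:
    """PRR, ROR, CIs, and the signal verdict for one table."""
    _, corrected = _maybe_correct(t, continuity)
    p = prr(t, continuity)
    r = ror(t, continuity)
    return DisproResult(
        table=t,
        prr=p.point,
        prr_ci_low=p.ci_low,
        prr_ci_high=p.ci_high,
        ror=r.point,
        ror_ci_low=r.ci_low,
        ror_ci_high=r.ci_high,
        is_signal=classify_signal(p, r),
        continuity_corrected=corrected,
        defined=p.defined and r.defined,
    )


def build_table(
    exposed: Iterable[IcsrRecord],
    comparator: Iterable[IcsrRecord],
    event_pts: Iterable[str],
    term: str = "",
    level: str = "PT",
    comparator_name: str = "",
) -> ContingencyTable:
    """Count the 2x2 cells for one event-term set.

    A report counts in the event cell when any of its reaction PTs falls in
    ``event_pts``; a report with several PTs inside one SOC/SMQ still counts
    once for that term.
    """
    pts = {p.strip().casefold() for p in event_pts}
    if not pts:
        raise ConfigurationError("event_pts must be non-empty")
    exposed = list(exposed)
    comparator = list(comparator)
    a = sum(1 for r in exposed if {x.strip().casefold() for x in r.reactions} & pts)
    c = sum(1 for r in comparator if {x.strip().casefold() for x in r.reactions} & pts)
    return ContingencyTable(
        a=a, b=len(exposed) - a, c=c, d=len(comparator) - c,
        term=term, level=level, comparator=comparator_name,
    )


def _term_event_sets(
    exposed: list[IcsrRecord], dictionary: MeddraDictionary, level: str
) -> dict[str, set[str]]:
    if level == "SOC":
        return {soc: dictionary.pts_for_soc(soc) for soc in sorted(dictionary.soc_names)}
    if level == "SMQ":
        out = {}
        for smq in dictionary.smq_names():
            pts = dictionary.pts_for_smq(smq, scope="narrow", level=1)
            if pts:
                out[smq] = pts
        return out
    if level == "PT":
        observed = sorted({p.strip() for r in exposed for p in r.reactions})
        return {p: {p} for p in observed}
    raise ConfigurationError(f"level must be one of {LEVELS}")


def analyze_level(
    exposed: Iterable[IcsrRecord],
    comparator: Iterable[IcsrRecord],
    dictionary: MeddraDictionary,
    level: str,
    min_exposed_reports: int = 100,
    continuity: str = "none",
    comparator_name: str = "",
) -> list[DisproResult]:
    """One disproportionality result per term at the given MedDRA level.

    PT-level terms enter only when reported in at least
    ``min_exposed_reports`` exposed reports (default 100); SOC/SMQ terms
    enter with at least one exposed report. Results sort by descending ROR,
    ties by descending A cell, then term text; undefined RORs sort last.
    """
    exposed = list(exposed)
    comparator = list(comparator)
    min_a = min_exposed_reports if level == "PT" else 1
    results = []
    for term, pts in _term_event_sets(exposed, dictionary, level).items():
        t = build_table(exposed, comparator, pts, term=term, level=level, comparator_name=comparator_name)
        if t.a < min_a:
            continue
        results.append(disproportionality(t, continuity))
    results.sort(
        key=lambda r: (
            -(r.ror if not math.isnan(r.ror) else -math.inf),
            -r.table.a,
            r.table.term,
        )
    )
    return results
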