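"""Reading and writing FAERS-style dollar-delimited quarterly tables.

Each FAERS quarter ships seven ASCII tables — DEMO (demographics), DRUG,
INDI (indications), OUTC (outcomes), REAC (reactions), RPSR (report
sources), THER (therapy dates) — delimited by ``$`` with one header line.
Column names drifted across eras (e.g. ``gndr_cod`` became ``sex``); a
built-in, user-overridable alias map normalizes them. Rows whose field
count disagrees with the header are collected into a rejects report with
line numbers rather than silently dropped: real FAERS files contain stray
delimiters and silent drops are unauditable.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

from .records import (
    AGE_UNIT_CODES,
    OCCUPATION_CODES,
    OUTCOME_CODES,
    REPORT_TYPE_CODES,
    REPORT_TYPE_TO_CODE,
    ROLE_CODES,
    DrugEntry,
    FuzzyDate,
    IcsrRecord,
)

TABLE_KINDS = ("DEMO", "DRUG", "INDI", "OUTC", "REAC", "RPSR", "THER")

#: Canonical columns consumed per table kind (extra columns are carried
#: through but ignored by assembly).
REQUIRED_COLUMNS = {
    "DEMO": ("primaryid", "caseid"),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "INDI": ("primaryid", "indi_drug_seq", "indi_pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "REAC": ("primaryid", "pt"),
    "RPSR": ("primaryid", "rpsr_cod"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt"),
}

#: Built-in alias map covering the column renames FAERS made across eras.
DEFAULT_ALIASES = {
    "gndr_cod": "sex",
    "case": "caseid",
    "caseversion": "caseversion",
    "drugname1": "drugname",
    "outc_code": "outc_cod",
}


@dataclass
class RejectedRow:
    line_number: int
    reason: str
    raw_line: str


@dataclass
class RawTable:
    """One parsed dollar-delimited table with canonical column names."""

    kind: str
    header: list[str]
    rows: list[tuple[str, ...]]
    quarter_label: str = ""
    rejects: list[RejectedRow] = field(default_factory=list)

    def column(self, name: str) -> int:
        return self.header.index(name)

    def to_text(self) -> str:
        lines = ["$".join(self.header)]
        for row in self.rows:
            lines.append("$".join(row))
        return "\n".join(lines) + "\n"


class FaersFormatError(ValueError):
    """Structural problem in an input table (missing column, bad header)."""


class DuplicatePrimaryIdError(FaersFormatError):
    """A DEMO table carried the same primary id twice (violates the FAERS
    contract that primary id identifies one report version)."""


def _open_source(source: Union[str, os.PathLike, IO[str]]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    if isinstance(source, (str, os.PathLike)) and os.path.exists(os.fspath(source)):
        # FAERS files are nominally ASCII but stray Latin-1 bytes occur.
        return open(source, "r", encoding="utf-8", errors="replace")
    if isinstance(source, str):
        return io.StringIO(source)
    raise FaersFormatError(f"cannot read table source {source!r}")


def parse_quarter_table(
    source: Union[str, os.PathLike, IO[str]],
    kind: str,
    aliases: Optional[dict[str, str]] = None,
    quarter_label: str = "",
) -> RawTable:
    """Parse one dollar-delimited table into a :class:`RawTable`.

    ``source`` may be a path, an open text stream, or the raw content
    itself. ``aliases`` maps era-specific column names to canonical ones and
    extends the built-in map. Field values are whitespace-trimmed; empty
    strings denote missing. Rows with a wrong field count go to
    ``RawTable.rejects``.
    """
    kind = kind.upper()
    if kind not in TABLE_KINDS:
        raise FaersFormatError(f"unknown table kind {kind!r}; expected one of {TABLE_KINDS}")
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update(aliases)

    stream = _open_source(source)
    header_line = stream.readline()
    if header_line == "":
        raise FaersFormatError(f"{kind}: empty input, no header line")
    header = [alias_map.get(h.strip().lower(), h.strip().lower()) for h in header_line.rstrip("\n\r").split("$")]
    if len(set(header)) != len(header):
        raise FaersFormatError(f"{kind}: duplicate column names after alias normalization: {header}")
    for col in REQUIRED_COLUMNS[kind]:
        if col not in header:
            raise FaersFormatError(f"{kind}: missing required column {col!r} (header: {header})")

    ncol = len(header)
    rows: list[tuple[str, ...]] = []
    rejects: list[RejectedRow] = []
    for lineno, line in enumerate(stream, start=2):
        line = line.rstrip("\n\r")
        if line == "":
            continue
        fields = line.split("$")
        if len(fields) != ncol:
            rejects.append(
                RejectedRow(lineno, f"expected {ncol} fields, found {len(fields)}", line)
            )
            continue
        rows.append(tuple(f.strip() for f in fields))
    return RawTable(kind=kind, header=header, rows=rows, quarter_label=quarter_label, rejects=rejects)


def _get(row: tuple[str, ...], table: RawTable, col: str) -> str:
    try:
        return row[table.column(col)]
    except ValueError:
        return ""


@dataclass
class AssembledCorpus:
    """Result of joining the quarterly tables into per-report records."""

    records: list[IcsrRecord]
    #: primary ids seen in child tables but absent from DEMO
    orphans: dict[str, set[str]] = field(default_factory=dict)
    rejects: list[tuple[str, RejectedRow]] = field(default_factory=list)


def assemble_icsrs(tables: Iterable[RawTable]) -> AssembledCorpus:
    """Join DEMO/DRUG/INDI/OUTC/REAC/THER/RPSR tables into ICSR records.

    One record per DEMO row, child rows attached by primary id (INDI
    attached to drugs by drug sequence number). Primary ids present only in
    child tables are reported as orphans per kind. A duplicate primary id
    within DEMO raises :class:`DuplicatePrimaryIdError`.
    """
    by_kind: dict[str, list[RawTable]] = {}
    for t in tables:
        by_kind.setdefault(t.kind, []).append(t)
    for needed in ("DEMO", "DRUG", "REAC"):
        if needed not in by_kind:
            raise FaersFormatError(f"assembly requires a {needed} table")

    records: dict[str, IcsrRecord] = {}
    rejects: list[tuple[str, RejectedRow]] = []
    for t in by_kind.get("DEMO", []):
        rejects.extend((t.kind, r) for r in t.rejects)
        for row in t.rows:
            pid = _get(row, t, "primaryid")
            if pid in records:
                raise DuplicatePrimaryIdError(f"primary id {pid} appears twice in DEMO")
            case_id = _get(row, t, "caseid")
            version_str = _get(row, t, "caseversion")
            if version_str:
                version = int(version_str)
            elif case_id and pid.startswith(case_id) and pid[len(case_id):].isdigit():
                version = int(pid[len(case_id):])
            else:
                version = 1
            age_raw = _get(row, t, "age")
            age_value = float(age_raw) if _is_number(age_raw) else None
            age_unit = _get(row, t, "age_cod").upper() or None
            if age_unit is not None and age_unit not in AGE_UNIT_CODES:
                age_unit = None
            sex_raw = _get(row, t, "sex").upper()
            sex = sex_raw if sex_raw in ("F", "M") else "unknown"
            records[pid] = IcsrRecord(
                primary_id=pid,
                case_id=case_id,
                case_version=version,
                event_date=FuzzyDate.parse(_get(row, t, "event_dt")),
                fda_receipt_date=FuzzyDate.parse(_get(row, t, "fda_dt")),
                age_value=age_value,
                age_unit=age_unit,
                sex=sex,
                reporter_country=_get(row, t, "reporter_country") or None,
                report_type=REPORT_TYPE_CODES.get(_get(row, t, "rept_cod").upper(), "unknown"),
                reporter_occupation=OCCUPATION_CODES.get(_get(row, t, "occp_cod").upper(), "unknown"),
            )

    orphans: dict[str, set[str]] = {}

    def record_for(pid: str, kind: str) -> Optional[IcsrRecord]:
        rec = records.get(pid)
        if rec is None:
            orphans.setdefault(kind, set()).add(pid)
        return rec

    for t in by_kind.get("DRUG", []):
        rejects.extend((t.kind, r) for r in t.rejects)
        for row in t.rows:
            rec = record_for(_get(row, t, "primaryid"), "DRUG")
            if rec is None:
                continue
            seq_raw = _get(row, t, "drug_seq")
            role = _get(row, t, "role_cod").upper()
            rec.drugs.append(
                DrugEntry(
                    drug_seq=int(seq_raw) if seq_raw.isdigit() else len(rec.drugs) + 1,
                    role=role if role in ROLE_CODES else "C",
                    raw_name=_get(row, t, "drugname"),
                    active_ingredient=_get(row, t, "prod_ai") or None,
                )
            )
    for t in by_kind.get("INDI", []):
        rejects.extend((t.kind, r) for r in t.rejects)
        for row in t.rows:
            rec = record_for(_get(row, t, "primaryid"), "INDI")
            if rec is None:
                continue
            seq_raw = _get(row, t, "indi_drug_seq")
            term = _get(row, t, "indi_pt")
            if not seq_raw.isdigit() or not term:
                continue
            seq = int(seq_raw)
            for drug in rec.drugs:
                if drug.drug_seq == seq:
                    drug.indications.add(term)
                    break
    for t in by_kind.get("REAC", []):
        rejects.extend((t.kind, r) for r in t.rejects)
        for row in t.rows:
            rec = record_for(_get(row, t, "primaryid"), "REAC")
            if rec is not None and _get(row, t, "pt"):
                rec.reactions.add(_get(row, t, "pt"))
    for t in by_kind.get("OUTC", []):
        rejects.extend((t.kind, r) for r in t.rejects)
        for row in t.rows:
            rec = record_for(_get(row, t, "primaryid"), "OUTC")
            code = _get(row, t, "outc_cod").upper()
            if rec is not None and code in OUTCOME_CODES:
                rec.outcomes.add(code)
    for t in by_kind.get("THER", []):
        rejects.extend((t.kind, r) for r in t.rejects)
        for row in t.rows:
            rec = record_for(_get(row, t, "primaryid"), "THER")
            if rec is None:
                continue
            seq_raw = _get(row, t, "dsg_drug_seq")
            if seq_raw.isdigit():
                rec.therapy_starts[int(seq_raw)] = FuzzyDate.parse(_get(row, t, "start_dt"))
    for t in by_kind.get("RPSR", []):
        rejects.extend((t.kind, r) for r in t.rejects)
        for row in t.rows:
            rec = record_for(_get(row, t, "primaryid"), "RPSR")
            if rec is not None and _get(row, t, "rpsr_cod"):
                rec.report_sources.add(_get(row, t, "rpsr_cod").upper())

    ordered = sorted(records.values(), key=lambda r: r.primary_id)
    return AssembledCorpus(records=ordered, orphans=orphans, rejects=rejects)


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


_SEX_TO_FIELD = {"F": "F", "M": "M", "unknown": "UNK"}
_OCC_TO_CODE = {"consumer": "CN", "physician": "MD", "pharmacist": "PH", "other": "OT"}
_AGE_FMT = lambda v: ("%g" % v)


def serialize_icsrs(records: Iterable[IcsrRecord], quarter_label: str = "") -> dict[str, RawTable]:
    """Serialize records back into the seven canonical tables.

    Inverse of :func:`assemble_icsrs` on clean inputs: re-parsing the
    emitted tables yields field-for-field identical records.
    """
    demo_rows, drug_rows, indi_rows, outc_rows, reac_rows, ther_rows, rpsr_rows = (
        [], [], [], [], [], [], []
    )
    for rec in sorted(records, key=lambda r: r.primary_id):
        demo_rows.append(
            (
                rec.primary_id,
                rec.case_id,
                str(rec.case_version),
                rec.event_date.faers_str() if rec.event_date else "",
                rec.fda_receipt_date.faers_str() if rec.fda_receipt_date else "",
                _AGE_FMT(rec.age_value) if rec.age_value is not None else "",
                rec.age_unit or "",
                _SEX_TO_FIELD.get(rec.sex, "UNK"),
                rec.reporter_country or "",
                REPORT_TYPE_TO_CODE.get(rec.report_type, ""),
                _OCC_TO_CODE.get(rec.reporter_occupation, ""),
            )
        )
        for d in sorted(rec.drugs, key=lambda d: d.drug_seq):
            drug_rows.append(
                (rec.primary_id, rec.case_id, str(d.drug_seq), d.role, d.raw_name, d.active_ingredient or "")
            )
            for term in sorted(d.indications):
                indi_rows.append((rec.primary_id, rec.case_id, str(d.drug_seq), term))
        for code in sorted(rec.outcomes):
            outc_rows.append((rec.primary_id, rec.case_id, code))
        for term in sorted(rec.reactions):
            reac_rows.append((rec.primary_id, rec.case_id, term))
        for seq in sorted(rec.therapy_starts):
            start = rec.therapy_starts[seq]
            ther_rows.append((rec.primary_id, rec.case_id, str(seq), start.faers_str() if start else ""))
        for src in sorted(rec.report_sources):
            rpsr_rows.append((rec.primary_id, rec.case_id, src))

    return {
        "DEMO": RawTable(
            "DEMO",
            [
                "primaryid", "caseid", "caseversion", "event_dt", "fda_dt",
                "age", "age_cod", "sex", "reporter_country", "rept_cod", "occp_cod",
            ],
            demo_rows,
            quarter_label,
        ),
        "DRUG": RawTable(
            "DRUG", ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"], drug_rows, quarter_label
        ),
        "INDI": RawTable("INDI", ["primaryid", "caseid", "indi_drug_seq", "indi_pt"], indi_rows, quarter_label),
        "OUTC": RawTable("OUTC", ["primaryid", "caseid", "outc_cod"], outc_rows, quarter_label),
        "REAC": RawTable("REAC", ["primaryid", "caseid", "pt"], reac_rows, quarter_label),
        "THER": RawTable("THER", ["primaryid", "caseid", "dsg_drug_seq", "start_dt"], ther_rows, quarter_label),
        "RPSR": RawTable("RPSR", ["primaryid", "caseid", "rpsr_cod"], rpsr_rows, quarter_label),
    }


def write_tables(tables: dict[str, RawTable], out_dir: Union[str, os.PathLike], quarter_label: str) -> list[str]:
    """Write tables in the FAERS file-naming convention (e.g. demo17q3.txt)."""
    os.makedirs(out_dir, exist_ok=True)
    suffix = quarter_label.lower().replace("20", "", 1) if len(quarter_label) == 6 else quarter_label.lower()
    paths = []
    for kind, table in tables.items():
        path = os.path.join(out_dir, f"{kind.lower()}{suffix}.txt")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(table.to_text())
        paths.append(path)
    return paths


def discover_tables(paths: Iterable[Union[str, os.PathLike]], aliases: Optional[dict[str, str]] = None) -> list[RawTable]:
    """Parse a set of quarterly files, inferring each file's table kind from
    its basename prefix (demo..., drug..., ...)."""
    tables = []
    for path in sorted(os.fspath(p) for p in paths):
        base = os.path.basename(path).lower()
        kind = next((k for k in TABLE_KINDS if base.startswith(k.lower())), None)
        if kind is None:
            raise FaersFormatError(f"cannot infer table kind from file name {base!r}")
        label = os.path.splitext(base)[0][len(kind):]
        tables.append(parse_quarter_table(path, kind, aliases=aliases, quarter_label=label))
    return tables
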