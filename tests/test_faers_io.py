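"""Parsing, assembly, and round-trip of the dollar-delimited tables."""

from __future__ import annotations

import pytest

from faers_signal.faers_io import (
    DuplicatePrimaryIdError,
    FaersFormatError,
    assemble_icsrs,
    parse_quarter_table,
    serialize_icsrs,
)

DEMO_HEADER = "primaryid$caseid$caseversion$event_dt$fda_dt$age$age_cod$sex$reporter_country$rept_cod$occp_cod"


def test_header_only_stream_yields_empty_table():
    table = parse_quarter_table("primaryid$caseid$caseversion\n", "DEMO")
    assert table.rows == [] and table.rejects == []


def test_demo_row_parses_to_expected_record():
    text = (
        "primaryid$caseid$caseversion$event_dt$age$age_cod$sex\n"
        "100000011$10000001$1$20170102$54$YR$F\n"
    )
    corpus = assemble_icsrs(
        [
            parse_quarter_table(text, "DEMO"),
            parse_quarter_table("primaryid$drug_seq$role_cod$drugname\n", "DRUG"),
            parse_quarter_table("primaryid$pt\n", "REAC"),
        ]
    )
    (rec,) = corpus.records
    assert rec.primary_id == "100000011"
    assert rec.case_id == "10000001" and rec.case_version == 1
    assert rec.age_value == 54 and rec.age_unit == "YR"
    assert rec.sex == "F"
    assert (rec.event_date.year, rec.event_date.month, rec.event_date.day) == (2017, 1, 2)


def test_legacy_gndr_cod_alias_equivalent_to_sex_column():
    modern = "primaryid$caseid$caseversion$sex\n100000011$10000001$1$F\n"
    legacy = "primaryid$caseid$caseversion$gndr_cod\n100000011$10000001$1$F\n"
    t_modern = parse_quarter_table(modern, "DEMO")
    t_legacy = parse_quarter_table(legacy, "DEMO")
    assert t_modern.header == t_legacy.header
    assert t_modern.rows == t_legacy.rows


def test_missing_required_column_names_the_column():
    with pytest.raises(FaersFormatError, match="caseid"):
        parse_quarter_table("primaryid$sex\n", "DEMO")


def test_wrong_field_count_goes_to_rejects_not_dropped_silently():
    text = "primaryid$caseid$caseversion\n1001$100$1\n1002$100$1$EXTRA\n1003$100$1\n"
    table = parse_quarter_table(text, "DEMO")
    assert len(table.rows) == 2
    assert len(table.rejects) == 1
    assert table.rejects[0].line_number == 3
    assert "4" in table.rejects[0].reason


def test_values_are_trimmed_and_empty_becomes_missing():
    text = "primaryid$caseid$caseversion$age$age_cod$sex\n1001$100$1$ 54 $$\n"
    corpus = assemble_icsrs(
        [
            parse_quarter_table(text, "DEMO"),
            parse_quarter_table("primaryid$drug_seq$role_cod$drugname\n", "DRUG"),
            parse_quarter_table("primaryid$pt\n", "REAC"),
        ]
    )
    rec = corpus.records[0]
    assert rec.age_value == 54 and rec.age_unit is None and rec.sex == "unknown"


def _toy_tables():
    demo = parse_quarter_table(
        DEMO_HEADER + "\n100000011$10000001$1$20170102$20170301$54$YR$F$US$EXP$MD\n",
        "DEMO",
    )
    drug = parse_quarter_table(
        "primaryid$drug_seq$role_cod$drugname$prod_ai\n"
        "100000011$1$PS$COSENTYX$secukinumab\n"
        "100000011$2$SS$METHOTREXATE$\n",
        "DRUG",
    )
    indi = parse_quarter_table(
        "primaryid$indi_drug_seq$indi_pt\n100000011$2$Psoriasis\n", "INDI"
    )
    reac = parse_quarter_table(
        "primaryid$pt\n100000011$Pyrexia\n100000011$Nausea\n", "REAC"
    )
    outc = parse_quarter_table(
        "primaryid$outc_cod\n100000011$DE\n100000011$HO\n", "OUTC"
    )
    return [demo, drug, indi, reac, outc]


def test_assembly_joins_children_by_primary_id_and_drug_seq():
    (rec,) = assemble_icsrs(_toy_tables()).records
    assert rec.reactions == {"Pyrexia", "Nausea"}
    # INDI row with indi_drug_seq 2 attaches to the drug with seq 2 only
    assert rec.drugs[0].indications == set()
    assert rec.drugs[1].indications == {"Psoriasis"}
    # one report can carry several outcomes; each is kept
    assert rec.outcomes == {"DE", "HO"}


def test_orphan_child_rows_are_reported():
    tables = _toy_tables()
    tables.append(parse_quarter_table("primaryid$pt\n999999991$Rash\n", "REAC"))
    corpus = assemble_icsrs(tables)
    assert corpus.orphans == {"REAC": {"999999991"}}


def test_duplicate_primary_id_in_demo_is_an_error():
    demo = parse_quarter_table(
        "primaryid$caseid$caseversion\n1001$100$1\n1001$100$1\n", "DEMO"
    )
    drug = parse_quarter_table("primaryid$drug_seq$role_cod$drugname\n", "DRUG")
    reac = parse_quarter_table("primaryid$pt\n", "REAC")
    with pytest.raises(DuplicatePrimaryIdError):
        assemble_icsrs([demo, drug, reac])


@pytest.mark.parametrize(
    "text,expected",
    [
        ("20170102", ("day", 2017, 1, 2)),
        ("201701", ("month", 2017, 1, None)),
        ("2017", ("year", 2017, None, None)),
    ],
)
def test_partial_dates_kept_at_reduced_precision(text, expected):
    from faers_signal.records import FuzzyDate

    d = FuzzyDate.parse(text)
    assert (d.precision, d.year, d.month, d.day) == expected
    assert FuzzyDate.parse(d.faers_str()) == d
    assert (d.to_date() is not None) == (d.precision == "day")


def test_invalid_dates_become_missing():
    from faers_signal.records import FuzzyDate

    assert FuzzyDate.parse("20171345") is None
    assert FuzzyDate.parse("notadate") is None
    assert FuzzyDate.parse("") is None


def test_round_trip_serialize_reparse_identical(small_corpus):
    """Serializing an assembled record set back to the seven tables and
    re-parsing yields a field-for-field identical record set."""
    records = small_corpus.records
    tables = serialize_icsrs(records, quarter_label="2017Q1")
    reparsed = assemble_icsrs(
        [parse_quarter_table(t.to_text(), kind) for kind, t in tables.items()]
    )
    assert len(reparsed.records) == len(records)
    originals = {r.primary_id: r for r in records}
    for rec in reparsed.records:
        orig = originals[rec.primary_id]
        assert rec.case_id == orig.case_id
        assert rec.case_version == orig.case_version
        assert rec.event_date == orig.event_date
        assert rec.fda_receipt_date == orig.fda_receipt_date
        assert rec.age_value == orig.age_value and rec.age_unit == orig.age_unit
        assert rec.sex == orig.sex
        assert rec.reporter_country == orig.reporter_country
        assert rec.report_type == orig.report_type
        assert rec.reporter_occupation == orig.reporter_occupation
        assert rec.reactions == orig.reactions
        assert rec.outcomes == orig.outcomes
        assert rec.therapy_starts == orig.therapy_starts
        assert [(d.drug_seq, d.role, d.raw_name, d.indications) for d in rec.drugs] == [
            (d.drug_seq, d.role, d.raw_name, d.indications) for d in orig.drugs
        ]


def test_record_count_equals_demo_rows_minus_rejects(small_corpus):
    tables = serialize_icsrs(small_corpus.records)
    demo_text = tables["DEMO"].to_text()
    # corrupt two DEMO lines with a stray delimiter
    lines = demo_text.splitlines()
    lines[3] += "$stray"
    lines[7] += "$stray"
    demo = parse_quarter_table("\n".join(lines) + "\n", "DEMO")
    corpus = assemble_icsrs(
        [demo] + [parse_quarter_table(t.to_text(), k) for k, t in tables.items() if k != "DEMO"]
    )
    assert len(demo.rejects) == 2
    assert len(corpus.records) == len(small_corpus.records) - 2
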