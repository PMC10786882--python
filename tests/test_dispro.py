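"""PRR/ROR point estimates, confidence intervals, and signal rules."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faers_signal.dispro import (
    ConfigurationError,
    ContingencyTable,
    RatioEstimate,
    analyze_level,
    build_table,
    classify_signal,
    disproportionality,
    prr,
    ror,
)

from conftest import make_record


def oracle_prr(a, b, c, d):
    """Independent hand-coded evaluation of the PRR formula and its
    log-normal CI."""
    point = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return point, math.exp(math.log(point) - 1.96 * se), math.exp(math.log(point) + 1.96 * se)


def oracle_ror(a, b, c, d):
    """Independent hand-coded Woolf odds-ratio oracle."""
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return point, math.exp(math.log(point) - 1.96 * se), math.exp(math.log(point) + 1.96 * se)


def test_worked_formula_case():
    t = ContingencyTable(10, 90, 10, 900)
    r = ror(t)
    p = prr(t)
    assert r.point == pytest.approx(10.0, abs=1e-12)
    assert p.point == pytest.approx(9.1, abs=1e-12)
    assert r.ci_low == pytest.approx(4.05, abs=5e-3)
    assert r.ci_high == pytest.approx(24.67, abs=5e-3)


def test_equal_proportions_give_unity():
    assert prr(ContingencyTable(5, 5, 50, 50)).point == pytest.approx(1.0)
    for k in (1, 3, 17):
        est = ror(ContingencyTable(k, k, k, k))
        assert est.point == pytest.approx(1.0)
        assert est.ci_low < 1 < est.ci_high


def test_formula_oracle_on_random_tables():
    """1,000 seeded random tables: points and CIs match the independent
    oracle to relative error < 1e-12."""
    rng = np.random.default_rng(2024)
    checked = 0
    for _ in range(1000):
        a, b, c, d = (int(x) for x in rng.integers(0, 501, size=4))
        if a + b == 0 or c + d == 0:
            continue
        t = ContingencyTable(a, b, c, d)
        p, r = prr(t), ror(t)
        if min(a, b, c, d) > 0:
            for got, want in zip(
                (p.point, p.ci_low, p.ci_high), oracle_prr(a, b, c, d)
            ):
                assert abs(got - want) <= 1e-12 * abs(want)
            for got, want in zip(
                (r.point, r.ci_low, r.ci_high), oracle_ror(a, b, c, d)
            ):
                assert abs(got - want) <= 1e-12 * abs(want)
            checked += 1
        else:
            assert not (p.defined and r.defined)
    assert checked > 800


def test_cross_check_against_statsmodels_table2x2():
    """Independent library cross-check: statsmodels' log-OR machinery
    agrees with our Woolf CI up to its use of the exact normal quantile."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(7)
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(1, 400, size=4))
        t2 = sm.stats.Table2x2([[a, b], [c, d]], shift_zeros=False)
        est = ror(ContingencyTable(a, b, c, d))
        assert est.point == pytest.approx(t2.oddsratio, rel=1e-12)
        lo, hi = t2.oddsratio_confint(0.05)
        # 1.96 vs norm.ppf(0.975)=1.95996...: sub-0.1% CI difference
        assert est.ci_low == pytest.approx(lo, rel=2e-3)
        assert est.ci_high == pytest.approx(hi, rel=2e-3)


def test_zero_cell_policies():
    t = ContingencyTable(0, 10, 5, 95)
    p = prr(t)
    assert p.point == 0.0 and not p.defined and math.isnan(p.ci_low)
    r = ror(ContingencyTable(5, 10, 0, 95))
    assert not r.defined
    corrected = ror(ContingencyTable(0, 10, 0, 10), continuity="halves")
    assert corrected.point == pytest.approx(1.0)
    res = disproportionality(ContingencyTable(0, 10, 0, 10), continuity="halves")
    assert res.continuity_corrected


def test_invalid_tables_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 5, 5, 5)
    with pytest.raises(ValueError):
        ContingencyTable(0, 0, 5, 5)


@given(
    st.integers(1, 400), st.integers(1, 400), st.integers(1, 400), st.integers(1, 400)
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_ror_symmetry_under_group_swap(a, b, c, d):
    """Swapping exposed and comparator inverts the ROR and mirrors its CI."""
    fwd = ror(ContingencyTable(a, b, c, d))
    rev = ror(ContingencyTable(c, d, a, b))
    assert rev.point == pytest.approx(1 / fwd.point, rel=1e-12)
    assert rev.ci_low == pytest.approx(1 / fwd.ci_high, rel=1e-12)
    assert rev.ci_high == pytest.approx(1 / fwd.ci_low, rel=1e-12)


@given(st.integers(1, 200), st.integers(1, 200), st.integers(1, 200), st.integers(1, 200))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_monotonicity_in_a(a, b, c, d):
    """More exposed events with everything else fixed strictly raises both
    statistics."""
    t_lo = ContingencyTable(a, b, c, d)
    t_hi = ContingencyTable(a + 1, b, c, d)
    assert prr(t_hi).point > prr(t_lo).point
    assert ror(t_hi).point > ror(t_lo).point


@pytest.mark.parametrize(
    "prr_pt,ror_pt,ci_low,expected",
    [
        (3.0, 3.2, 1.4, True),
        (1.9, 3.2, 1.4, False),  # PRR criterion fails
        (2.5, 2.5, 1.0, False),  # strict inequality at the CI bound
        (2.5, 2.5, 1.0001, True),
        (2.0, 2.5, 1.4, False),  # strict inequality on PRR
        (2.5, 2.0, 1.4, False),  # strict inequality on ROR
    ],
)
def test_signal_rule_boundaries(prr_pt, ror_pt, ci_low, expected):
    p = RatioEstimate(prr_pt, prr_pt / 2, prr_pt * 2)
    r = RatioEstimate(ror_pt, ci_low, ror_pt * 2)
    assert classify_signal(p, r) is expected


def test_undefined_statistics_are_never_signals():
    res = disproportionality(ContingencyTable(0, 10, 5, 95))
    assert not res.is_signal and not res.defined


def test_build_table_counts_each_report_once_per_term():
    exposed = [
        make_record("11", reactions={"Pyrexia", "Nausea"}),
        make_record("21", reactions={"Rash"}),
        make_record("31", reactions={"Headache"}),
    ]
    comparator = [
        make_record("41", reactions={"Pyrexia"}),
        make_record("51", reactions={"Nausea"}),
        make_record("61", reactions={"Rash"}),
        make_record("71", reactions={"Dizziness"}),
    ]
    # both of this record's PTs are in the event set: still one count
    t = build_table(exposed, comparator, {"Pyrexia", "Nausea"})
    assert (t.a, t.b, t.c, t.d) == (1, 2, 2, 2)
    t0 = build_table(exposed, comparator, {"Vertigo"})
    assert (t0.a, t0.c) == (0, 0) and (t0.b, t0.d) == (3, 4)
    with pytest.raises(ConfigurationError):
        build_table(exposed, comparator, set())


def test_build_table_matches_ledger_on_synthetic_corpus(small_corpus):
    """Generator-ledger oracle: the pipeline table over unique cases equals
    the ledger's per-pair recount."""
    canonical_ids = {c.case_id for c in small_corpus.ledger.cases}
    uniques = [
        r
        for r in small_corpus.records
        if r.case_id in canonical_ids and r.case_version == 1
    ]
    exposed = [r for r in uniques if any(d.active_ingredient == "secukinumab" for d in r.drugs)]
    comparator = [r for r in uniques if r not in exposed]
    got = build_table(exposed, comparator, {"Oral candidiasis"})
    want = small_corpus.ledger.contingency("secukinumab", "Oral candidiasis")
    assert (got.a, got.b, got.c, got.d) == (want.a, want.b, want.c, want.d)


def test_analyze_level_inclusion_rules_and_ordering(mini_dict):
    exposed = [make_record(f"{i}1", str(i), reactions={"Oral candidiasis"}) for i in range(99)]
    exposed += [make_record(f"x{i}1", f"x{i}", reactions={"Pyrexia"}) for i in range(150)]
    comparator = [make_record(f"c{i}1", f"c{i}", reactions={"Nausea"}) for i in range(300)]

    results = analyze_level(exposed, comparator, mini_dict, "PT", min_exposed_reports=100)
    assert [r.table.term for r in results] == ["Pyrexia"]  # 99-report PT excluded

    relaxed = analyze_level(exposed, comparator, mini_dict, "PT", min_exposed_reports=1)
    assert {r.table.term for r in relaxed} == {"Oral candidiasis", "Pyrexia"}

    soc_results = analyze_level(exposed, comparator, mini_dict, "SOC", min_exposed_reports=100)
    assert all(r.table.level == "SOC" and r.table.a >= 1 for r in soc_results)
    rors = [r.ror for r in soc_results if not math.isnan(r.ror)]
    assert rors == sorted(rors, reverse=True)


def test_soc_level_equals_brute_force_recount(small_corpus, mini_dict):
    canonical_ids = {c.case_id for c in small_corpus.ledger.cases}
    uniques = [r for r in small_corpus.records if r.case_id in canonical_ids and r.case_version == 1]
    exposed = [r for r in uniques if any(d.active_ingredient == "secukinumab" for d in r.drugs)]
    comparator = [r for r in uniques if not any(d.active_ingredient == "secukinumab" for d in r.drugs)]
    results = analyze_level(exposed, comparator, mini_dict, "SOC")
    by_term = {r.table.term: r.table for r in results}
    for soc in mini_dict.soc_names:
        pts = {p.casefold() for p in mini_dict.pts_for_soc(soc)}
        a = sum(1 for r in exposed if {x.casefold() for x in r.reactions} & pts)
        c = sum(1 for r in comparator if {x.casefold() for x in r.reactions} & pts)
        if a >= 1:
            assert (by_term[soc].a, by_term[soc].c) == (a, c)
            assert by_term[soc].b == len(exposed) - a
        else:
            assert soc not in by_term
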