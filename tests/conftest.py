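from __future__ import annotations

import pytest

from faers_signal import DrugCatalog, SimConfig, generate_corpus, load_dictionary, mini_meddra
from faers_signal.records import DrugEntry, FuzzyDate, IcsrRecord


@pytest.fixture(scope="session")
def catalog() -> DrugCatalog:
    return DrugCatalog()


@pytest.fixture(scope="session")
def mini_dict():
    pt_df, smq_df = mini_meddra(8, 40, 6, seed=1)
    return load_dictionary(pt_df.to_csv(sep="\t", index=False), smq_df.to_csv(sep="\t", index=False))


@pytest.fixture(scope="session")
def small_corpus():
    """300-case corpus with both duplicate mechanisms and one injected
    association, kept in memory."""
    config = SimConfig(
        n_cases=300,
        seed=11,
        version_dup_rate=0.2,
        crosssource_dup_rate=0.1,
        injected_associations=[("secukinumab", "Oral candidiasis", 4.0)],
    )
    return generate_corpus(config)


def make_record(
    primary_id: str = "100000011",
    case_id: str | None = None,
    version: int = 1,
    drugs: list[tuple[str, str, set[str]]] = (("COSENTYX", "PS", {"Psoriasis"}),),
    reactions: set[str] = frozenset({"Pyrexia"}),
    event_date: str | None = "20170102",
    fda_date: str | None = "20170301",
    age: float | None = 54,
    age_unit: str | None = "YR",
    sex: str = "F",
    country: str | None = "US",
    outcomes: set[str] = frozenset(),
) -> IcsrRecord:
    case_id = case_id if case_id is not None else primary_id[:-1]
    return IcsrRecord(
        primary_id=primary_id,
        case_id=case_id,
        case_version=version,
        event_date=FuzzyDate.parse(event_date) if event_date else None,
        fda_receipt_date=FuzzyDate.parse(fda_date) if fda_date else None,
        age_value=age,
        age_unit=age_unit,
        sex=sex,
        reporter_country=country,
        drugs=[
            DrugEntry(drug_seq=i + 1, role=role, raw_name=name, indications=set(inds))
            for i, (name, role, inds) in enumerate(drugs)
        ],
        reactions=set(reactions),
        outcomes=set(outcomes),
    )
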