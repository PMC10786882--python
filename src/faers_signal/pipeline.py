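"""End-to-end study orchestration from a single run configuration.

Stages, in order: parse quarterly tables -> assemble ICSRs -> case-version
dedup -> multifield dedup -> psoriasis-indication filter -> exposure-group
assignment -> descriptive summaries -> SOC/SMQ/PT disproportionality for
each configured comparator. Every stage logs its input/output counts into a
run manifest so the attrition funnel can be reconstructed, and all tabular
outputs are TSV with deterministic ordering: two runs on identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import glob as _glob
import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Union

import pandas as pd
import yaml

from . import dispro as dispro_mod
from . import summary as summary_mod
from .cohort import DEFAULT_INDICATION_TERMS, DrugCatalog, assign_groups, filter_psoriasis_reports, split_groups
from .dedup import MISSING_POLICIES, deduplicate
from .faers_io import discover_tables
from .meddra import load_dictionary
from .records import OUTCOME_CODES

COMPARATORS = ("other_biologics", "non_biologics")


class ConfigurationError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything a study run needs; loadable from YAML."""

    input_globs: list[str]
    pt_soc_table: str
    smq_table: Optional[str] = None
    indication_terms: list[str] = field(default_factory=lambda: sorted(DEFAULT_INDICATION_TERMS))
    catalog_path: Optional[str] = None
    missing_policy: str = "missing_matches"
    strict_indication: bool = True
    min_exposed_reports: int = 100
    continuity: str = "none"
    comparators: list[str] = field(default_factory=lambda: list(COMPARATORS))
    output_dir: str = "faers_signal_out"
    decimals: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not self.input_globs:
            raise ConfigurationError("input_globs must be non-empty")
        if self.missing_policy not in MISSING_POLICIES:
            raise ConfigurationError(f"missing_policy must be one of {MISSING_POLICIES}")
        for comp in self.comparators:
            if comp not in COMPARATORS:
                raise ConfigurationError(f"unknown comparator {comp!r}; expected one of {COMPARATORS}")
        if self.min_exposed_reports <= 0:
            raise ConfigurationError("min_exposed_reports must be positive")
        if not self.indication_terms:
            raise ConfigurationError("indication_terms must be non-empty")
        if not os.path.exists(self.pt_soc_table):
            raise ConfigurationError(f"pt_soc_table not found: {self.pt_soc_table}")
        if self.smq_table is not None and not os.path.exists(self.smq_table):
            raise ConfigurationError(f"smq_table not found: {self.smq_table}")

    @classmethod
    def from_yaml(cls, path: Union[str, os.PathLike]) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _fmt(x: float, decimals: int = 4) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.{decimals}f}"


def results_frame(results: list[dispro_mod.DisproResult]) -> pd.DataFrame:
    """Disproportionality results as the standard TSV columns (mirrors a
    forest-plot data table: counts, PRR/ROR with CIs, signal flag)."""
    return pd.DataFrame(
        {
            "term": [r.table.term for r in results],
            "level": [r.table.level for r in results],
            "comparator": [r.table.comparator for r in results],
            "a": [int(r.table.a) for r in results],
            "b": [int(r.table.b) for r in results],
            "c": [int(r.table.c) for r in results],
            "d": [int(r.table.d) for r in results],
            "prr": [_fmt(r.prr) for r in results],
            "prr_ci_low": [_fmt(r.prr_ci_low) for r in results],
            "prr_ci_high": [_fmt(r.prr_ci_high) for r in results],
            "ror": [_fmt(r.ror) for r in results],
            "ror_ci_low": [_fmt(r.ror_ci_low) for r in results],
            "ror_ci_high": [_fmt(r.ror_ci_high) for r in results],
            "signal": [("yes" if r.is_signal else "no") for r in results],
        }
    )


def summary_frame(s: summary_mod.GroupSummary, group: str) -> pd.DataFrame:
    """One GroupSummary flattened to (group, section, key, count, value)
    rows; every percentage is recomputable from its count and n."""
    rows: list[tuple[str, str, str, str, str]] = []

    def add(section: str, key: str, count, value) -> None:
        rows.append((group, section, str(key), "" if count is None else str(count), value))

    add("size", "n", s.n, str(s.n))
    for label, mi in [("all", s.age_overall)] + sorted(s.age_by_sex.items()):
        if mi.median is None:
            add("age_years", label, mi.n, "NA")
        else:
            add("age_years", label, mi.n, f"{_fmt(mi.median, 1)} ({_fmt(mi.iqr_low, 1)}-{_fmt(mi.iqr_high, 1)})")
    for sex in ("F", "M", "unknown"):
        add("sex", sex, s.sex_counts.get(sex, 0), summary_mod.format_percentage(s.sex_counts.get(sex, 0), s.n, s.decimals) if s.n else "")
    for code in OUTCOME_CODES:
        add("outcome", code, s.outcome_counts.get(code, 0), summary_mod.format_percentage(s.outcome_counts.get(code, 0), s.n, s.decimals) if s.n else "")
    for key in ("direct", "expedited", "non-expedited", "unknown"):
        add("report_type", key, s.report_type_counts.get(key, 0), summary_mod.format_percentage(s.report_type_counts.get(key, 0), s.n, s.decimals) if s.n else "")
    for key in ("consumer", "physician", "pharmacist", "other", "unknown"):
        add("reporter_occupation", key, s.reporter_occupation_counts.get(key, 0), summary_mod.format_percentage(s.reporter_occupation_counts.get(key, 0), s.n, s.decimals) if s.n else "")
    for year in sorted(s.yearly_counts):
        add("yearly", year, s.yearly_counts[year], summary_mod.format_percentage(s.yearly_counts[year], s.n, s.decimals) if s.n else "")
    if s.onset_days.median is not None:
        add("onset_days", "all", s.onset_days.n, f"{_fmt(s.onset_days.median, 0)} ({_fmt(s.onset_days.iqr_low, 0)}-{_fmt(s.onset_days.iqr_high, 0)})")
    add("onset_days", "negative_excluded", s.negative_onset_count, str(s.negative_onset_count))
    return pd.DataFrame(rows, columns=["group", "section", "key", "count", "value"])


@dataclass
class RunArtifacts:
    manifest: dict
    output_dir: str
    groups: dict[str, list]
    summaries: dict[str, summary_mod.GroupSummary]
    dispro_tables: dict[str, pd.DataFrame]


def run_study(config: RunConfig) -> RunArtifacts:
    """Execute the full workflow and write all run artifacts.

    Outputs under ``config.output_dir``: per-stage manifest (JSON),
    dedup audit TSV, parse-rejects TSV, cohort assignments TSV, per-group
    summary TSVs, and one disproportionality TSV per (level, comparator).
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}}

    def stage(name: str, count: int) -> None:
        manifest["stages"][name] = count

    paths = sorted(p for g in config.input_globs for p in _glob.glob(g))
    if not paths:
        raise ConfigurationError(f"no input files matched {config.input_globs}")
    tables = discover_tables(paths)
    corpus = cohort_assembled = None
    from .faers_io import assemble_icsrs  # deferred to keep import graph flat

    corpus = assemble_icsrs(tables)
    stage("assembled", len(corpus.records))

    rejects_df = pd.DataFrame(
        [(kind, r.line_number, r.reason, r.raw_line) for kind, r in corpus.rejects],
        columns=["table", "line", "reason", "raw"],
    )
    rejects_df.to_csv(os.path.join(config.output_dir, "rejects.tsv"), sep="\t", index=False)

    catalog = DrugCatalog.from_yaml(config.catalog_path) if config.catalog_path else DrugCatalog()
    stage1, stage2 = deduplicate(corpus.records, missing_policy=config.missing_policy, catalog=catalog)
    stage("after_version_dedup", len(stage1.records))
    stage("after_multifield_dedup", len(stage2.records))
    audit_df = pd.DataFrame(
        [(e.removed_primary_id, e.survivor_primary_id, e.stage) for e in stage1.removed + stage2.removed],
        columns=["removed_primary_id", "survivor_primary_id", "stage"],
    )
    audit_df.to_csv(os.path.join(config.output_dir, "dedup_audit.tsv"), sep="\t", index=False)

    filtered = filter_psoriasis_reports(
        stage2.records, config.indication_terms, catalog, strict=config.strict_indication
    )
    stage("psoriasis_cohort", len(filtered))

    assignments = assign_groups(filtered, catalog)
    groups = split_groups(filtered, assignments)
    for name, recs in groups.items():
        stage(f"group_{name}", len(recs))
    pd.DataFrame(
        [
            (a.primary_id, int(a.in_secukinumab), int(a.in_other_biologics), int(a.in_non_biologics))
            for a in sorted(assignments, key=lambda a: a.primary_id)
        ],
        columns=["primary_id", "in_secukinumab", "in_other_biologics", "in_non_biologics"],
    ).to_csv(os.path.join(config.output_dir, "assignments.tsv"), sep="\t", index=False)

    dictionary = load_dictionary(config.pt_soc_table, config.smq_table)

    summaries = {}
    summary_frames = []
    for name, recs in groups.items():
        target = "secukinumab" if name == "secukinumab" else None
        s = summary_mod.summarize_group(recs, target_drug=target, decimals=config.decimals)
        summaries[name] = s
        summary_frames.append(summary_frame(s, name))
    pd.concat(summary_frames, ignore_index=True).to_csv(
        os.path.join(config.output_dir, "summaries.tsv"), sep="\t", index=False
    )

    dispro_tables = {}
    exposed = groups["secukinumab"]
    for comp_name in config.comparators:
        comparator = groups[comp_name]
        if not exposed or not comparator:
            continue
        for level in ("SOC", "SMQ", "PT"):
            results = dispro_mod.analyze_level(
                exposed,
                comparator,
                dictionary,
                level,
                min_exposed_reports=config.min_exposed_reports,
                continuity=config.continuity,
                comparator_name=comp_name,
            )
            frame = results_frame(results)
            key = f"dispro_{level.lower()}_{comp_name}"
            dispro_tables[key] = frame
            frame.to_csv(os.path.join(config.output_dir, f"{key}.tsv"), sep="\t", index=False)
            stage(f"{key}_terms", len(frame))

    manifest["unmapped_pt_lookups"] = int(sum(dictionary.unmapped_tally.values()))
    with open(os.path.join(config.output_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return RunArtifacts(
        manifest=manifest,
        output_dir=config.output_dir,
        groups=groups,
        summaries=summaries,
        dispro_tables=dispro_tables,
    )
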