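"""MedDRA-style term hierarchy: PT -> primary SOC, and SMQ membership.

MedDRA itself is licensed, so the dictionary is supplied by the user as two
open TSV tables:

* ``pt_soc_table``: columns ``pt``, ``soc``, ``primary_flag`` — one row per
  (PT, SOC) assignment; only rows flagged primary enter the PT->primary-SOC
  map (a PT may belong to several SOCs but has exactly one primary SOC).
* ``smq_table``: columns ``smq``, ``level``, ``scope``, ``pt`` — flattened
  Standardised MedDRA Query membership with the hierarchy level (1-5) and
  the scope tag (``narrow`` = highly specific, ``broad`` = sensitive).

PT text matching is case-insensitive and whitespace-normalized, with no
fuzzy matching: FAERS reaction terms are already MedDRA-coded and fuzziness
would corrupt counts.
"""

from __future__ import annotations

import difflib
import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

import pandas as pd

SCOPES = ("narrow", "broad")
LEVELS = (1, 2, 3, 4, 5)

_MISSING = None


class DictionaryIntegrityError(ValueError):
    """The supplied dictionary violates its own invariants (e.g. a PT with
    two primary SOCs)."""


class UnknownSmqError(KeyError):
    def __init__(self, smq: str, known: Iterable[str]):
        near = difflib.get_close_matches(smq, list(known), n=3)
        hint = f"; close matches: {near}" if near else ""
        super().__init__(f"unknown SMQ {smq!r}{hint}")
        self.smq = smq
        self.near_matches = near


def _norm(term: str) -> str:
    return " ".join(term.split()).casefold()


@dataclass
class MeddraDictionary:
    """PT -> primary SOC map plus SMQ membership with level and scope."""

    pt_to_primary_soc: dict[str, str] = field(default_factory=dict)
    smq_index: dict[str, set[tuple[str, str, int]]] = field(default_factory=dict)
    soc_names: set[str] = field(default_factory=set)
    #: display form of each normalized PT, for reports
    pt_display: dict[str, str] = field(default_factory=dict)
    #: PTs looked up but absent from the map, tallied for the run report
    unmapped_tally: dict[str, int] = field(default_factory=dict)

    def soc_of(self, pt: str) -> Optional[str]:
        """Primary SOC of ``pt``, or None for unmapped PTs (missing is a
        value, not an error; unmapped lookups are tallied)."""
        key = _norm(pt)
        soc = self.pt_to_primary_soc.get(key)
        if soc is None:
            self.unmapped_tally[key] = self.unmapped_tally.get(key, 0) + 1
        return soc

    def pts_for_smq(
        self,
        smq: str,
        scope: str = "narrow",
        level: Optional[int] = 1,
    ) -> set[str]:
        """PTs of an SMQ passing the scope/level filters.

        Defaults (narrow scope, level 1) match the usual signal-detection
        convention of taking only the most specific members. ``scope='any'``
        or ``level=None`` relax the respective filter. An SMQ whose members
        all fail the filters yields an empty set, not an error.
        """
        key = _norm(smq)
        if key not in self.smq_index:
            raise UnknownSmqError(smq, (self.smq_display.get(k, k) for k in self.smq_index))
        out = set()
        for pt, member_scope, member_level in self.smq_index[key]:
            if scope != "any" and member_scope != scope:
                continue
            if level is not None and member_level != level:
                continue
            out.add(self.pt_display.get(pt, pt))
        return out

    def smq_names(self) -> list[str]:
        return sorted(self.smq_display.get(k, k) for k in self.smq_index)

    #: display form of each normalized SMQ name
    smq_display: dict[str, str] = field(default_factory=dict)

    def pts_for_soc(self, soc: str) -> set[str]:
        """All PTs whose primary SOC is ``soc``."""
        return {
            self.pt_display.get(pt, pt)
            for pt, s in self.pt_to_primary_soc.items()
            if s == soc
        }


def _read_tsv(source: Union[str, os.PathLike, IO[str]]) -> pd.DataFrame:
    if hasattr(source, "read"):
        return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    if isinstance(source, (str, os.PathLike)) and os.path.exists(os.fspath(source)):
        return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    return pd.read_csv(io.StringIO(str(source)), sep="\t", dtype=str, keep_default_na=False)


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def load_dictionary(
    pt_soc_table: Union[str, os.PathLike, IO[str]],
    smq_table: Union[str, os.PathLike, IO[str], None] = None,
) -> MeddraDictionary:
    """Load the dictionary from the two TSV tables.

    Load order is irrelevant: the result is independent of input row order.
    A PT asserted primary in two different SOCs raises
    :class:`DictionaryIntegrityError`; an unknown scope or level token is a
    format error.
    """
    pt_df = _read_tsv(pt_soc_table)
    for col in ("pt", "soc", "primary_flag"):
        if col not in pt_df.columns:
            raise DictionaryIntegrityError(f"pt_soc_table missing column {col!r}")

    d = MeddraDictionary()
    for row in pt_df.itertuples(index=False):
        flag_raw = str(row.primary_flag).strip().casefold()
        if flag_raw in _TRUE:
            primary = True
        elif flag_raw in _FALSE:
            primary = False
        else:
            raise DictionaryIntegrityError(f"bad primary_flag value {row.primary_flag!r}")
        pt_key = _norm(str(row.pt))
        soc = " ".join(str(row.soc).split())
        d.pt_display.setdefault(pt_key, " ".join(str(row.pt).split()))
        d.soc_names.add(soc)
        if not primary:
            continue
        existing = d.pt_to_primary_soc.get(pt_key)
        if existing is not None and existing != soc:
            raise DictionaryIntegrityError(
                f"PT {row.pt!r} has two primary SOCs: {existing!r} and {soc!r}"
            )
        d.pt_to_primary_soc[pt_key] = soc

    if smq_table is not None:
        smq_df = _read_tsv(smq_table)
        for col in ("smq", "level", "scope", "pt"):
            if col not in smq_df.columns:
                raise DictionaryIntegrityError(f"smq_table missing column {col!r}")
        for row in smq_df.itertuples(index=False):
            scope = str(row.scope).strip().casefold()
            if scope not in SCOPES:
                raise DictionaryIntegrityError(f"unknown scope token {row.scope!r}")
            level_raw = str(row.level).strip()
            if not level_raw.isdigit() or int(level_raw) not in LEVELS:
                raise DictionaryIntegrityError(f"SMQ level must be an integer 1..5, got {row.level!r}")
            level = int(level_raw)
            smq_key = _norm(str(row.smq))
            pt_key = _norm(str(row.pt))
            d.smq_display.setdefault(smq_key, " ".join(str(row.smq).split()))
            d.pt_display.setdefault(pt_key, " ".join(str(row.pt).split()))
            members = d.smq_index.setdefault(smq_key, set())
            for existing_pt, existing_scope, existing_level in members:
                if existing_pt == pt_key and existing_level == level and existing_scope != scope:
                    raise DictionaryIntegrityError(
                        f"PT {row.pt!r} carries both scopes in SMQ {row.smq!r} at level {level}"
                    )
            members.add((pt_key, scope, level))
    return d


# Thin functional aliases mirroring the operation names used elsewhere.
def soc_of(dictionary: MeddraDictionary, pt: str) -> Optional[str]:
    return dictionary.soc_of(pt)


def pts_for_smq(dictionary: MeddraDictionary, smq: str, scope: str = "narrow", level: Optional[int] = 1) -> set[str]:
    return dictionary.pts_for_smq(smq, scope=scope, level=level)
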