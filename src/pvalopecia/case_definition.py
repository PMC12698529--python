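"""SMQ-based case definition and Primary-Suspect drug attribution.

Target cases are flagged when any of their reaction preferred terms (PTs)
matches a Standardized MedDRA Query term list — exact, case-insensitive PT
match, never substring, because MedDRA PTs are a controlled vocabulary.
Drug attribution is restricted by role code (Primary Suspect by default):
reports listing a drug only as Secondary Suspect, Concomitant or Interacting
do not count toward that drug's 2x2 cell, and each case contributes at most
once per drug.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .faers_io import CaseReport


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SmqTermList:
    """A named set of preferred terms with a scope (narrow or broad)."""

    name: str
    scope: str
    pts: frozenset  # case-folded match keys

    def __post_init__(self):
        if self.scope not in {"narrow", "broad"}:
            raise ConfigurationError(f"scope must be narrow|broad, got {self.scope!r}")
        if not self.pts:
            raise ConfigurationError("SMQ term list is empty")

    @classmethod
    def from_terms(cls, name: str, terms: Iterable[str], scope: str = "narrow") -> "SmqTermList":
        keys = frozenset(t.strip().casefold() for t in terms if t and t.strip())
        return cls(name=name, scope=scope, pts=keys)


def load_smq_csv(path: str | Path, name: str = "user SMQ", scope: str = "narrow") -> SmqTermList:
    """Load an SMQ term list from a CSV with columns ``pt`` and optional
    ``scope``; rows whose scope differs from the requested one are ignored."""
    terms = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if row.get("scope", scope).strip().casefold() not in {scope, ""}:
                continue
            terms.append(row["pt"])
    return SmqTermList.from_terms(name, terms, scope=scope)


def flag_event_cases(cases: Sequence[CaseReport], smq: SmqTermList) -> set:
    """Primaryids of cases whose reaction PTs intersect the SMQ term set.

    Monotone in the term list: adding PTs can only flag more cases.
    """
    if not smq.pts:
        raise ConfigurationError("empty SMQ term list")
    flagged = set()
    for case in cases:
        if any(pt.casefold() in smq.pts for pt in case.reaction_pts):
            flagged.add(case.primaryid)
    return flagged


@dataclass(frozen=True)
class DrugCaseIndex:
    """Per-drug case sets plus the event and population case sets.

    ``drug_cases[drug]`` holds the primaryids where the drug appears with an
    allowed role; every indexed id belongs to ``all_cases`` and the event set
    is a subset of the population, so each drug-event 2x2 cell counts a case
    at most once.
    """

    drug_cases: dict = field(default_factory=dict)  # drug_name -> frozenset of primaryids
    event_cases: frozenset = frozenset()
    all_cases: frozenset = frozenset()

    def __post_init__(self):
        if not self.event_cases <= self.all_cases:
            raise ValueError("event_cases must be a subset of all_cases")

    def drugs(self) -> list:
        return sorted(self.drug_cases)

    def __contains__(self, drug_name: str) -> bool:
        return drug_name in self.drug_cases


def build_drug_case_index(
    cases: Sequence[CaseReport],
    event_ids: set,
    role_filter: Iterable[str] = ("PS",),
) -> DrugCaseIndex:
    """Index de-duplicated cases by drug, keeping only allowed role codes."""
    roles = frozenset(role_filter)
    drug_cases: dict[str, set] = {}
    all_ids = set()
    for case in cases:
        all_ids.add(case.primaryid)
        for name in case.drug_names(roles):
            drug_cases.setdefault(name, set()).add(case.primaryid)
    return DrugCaseIndex(
        drug_cases={d: frozenset(s) for d, s in drug_cases.items()},
        event_cases=frozenset(event_ids) & frozenset(all_ids),
        all_cases=frozenset(all_ids),
    )


def exclude_indicated_drugs(index: DrugCaseIndex, exclusion_list: Iterable[str]) -> DrugCaseIndex:
    """Drop drugs that are themselves indicated for the target condition.

    A drug prescribed to treat the event attracts reports of treatment
    failure, which masquerade as adverse-event signals; removing such drugs
    leaves the event and population case sets untouched.
    """
    excluded = {e.strip().upper() for e in exclusion_list}
    kept = {d: s for d, s in index.drug_cases.items() if d.upper() not in excluded}
    return replace(index, drug_cases=kept)


def load_drug_list_csv(path: str | Path, column: str = "drug_name") -> list:
    with open(path, newline="", encoding="utf-8") as fh:
        return [row[column].strip() for row in csv.DictReader(fh) if row.get(column, "").strip()]
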