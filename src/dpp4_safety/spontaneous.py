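"""Case-level contingency tables from spontaneous-report streams.

A spontaneous reporting system stores one case per reported adverse-event
episode: a set of drugs (each labelled suspect or concomitant) and a set of
MedDRA-style preferred terms (PTs).  Disproportionality statistics operate on
the 2x2 table obtained by crossing membership in a drug class with membership
in an event group, counting *cases* (a case contributes at most one to each
cell no matter how many member drugs or terms it mentions).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

ROLE_SUSPECT = "suspect"
ROLE_CONCOMITANT = "concomitant"
_VALID_ROLES = {ROLE_SUSPECT, ROLE_CONCOMITANT}

REPORT_COLUMNS = ["case_id", "drug", "role", "event_pt"]


@dataclass(frozen=True)
class Report:
    """One case: its drugs with reporting roles, and its reported PTs."""

    case_id: str
    drugs: frozenset  # of (name, role) tuples
    events: frozenset  # of PT strings

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if not self.events:
            raise ValueError(f"case {self.case_id!r}: events must be non-empty")

    def drug_names(self, suspect_only: bool = False) -> set:
        return {
            name
            for name, role in self.drugs
            if not suspect_only or role == ROLE_SUSPECT
        }


@dataclass(frozen=True)
class DrugClass:
    """A named set of drug substances, optionally excluding combination products.

    Combination products are excluded by name (``combinations``) because
    fixed-dose combinations carry distinct trade/substance labels; when
    ``exclude_combinations`` is False those labels count as members too.
    """

    name: str
    members: frozenset
    exclude_combinations: bool = True
    combinations: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"drug class {self.name!r}: members must be non-empty")

    def matches(self, drug_name: str) -> bool:
        if self.exclude_combinations and drug_name in self.combinations:
            return False
        return drug_name in self.members or (
            not self.exclude_combinations and drug_name in self.combinations
        )


@dataclass(frozen=True)
class EventDefinition:
    """A named group of PTs, possibly composed of child definitions.

    Composite endpoints (e.g. major cardiovascular events = myocardial
    infarction plus stroke) are expressed through ``composed_of``; the
    effective term set is the union over own terms and all children.
    """

    name: str
    pt_terms: frozenset = field(default_factory=frozenset)
    composed_of: tuple = ()

    def __post_init__(self) -> None:
        if not self.all_terms():
            raise ValueError(f"event {self.name!r}: term set must be non-empty")

    def all_terms(self) -> frozenset:
        terms = set(self.pt_terms)
        for child in self.composed_of:
            terms |= child.all_terms()
        return frozenset(terms)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 case counts: joint cell, drug margin, event margin, grand total."""

    n11: int
    n1dot: int
    ndot1: int
    ndotdot: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n1dot, self.ndot1, self.ndotdot) < 0:
            raise ValueError("counts must be non-negative")
        if self.n11 > min(self.n1dot, self.ndot1):
            raise ValueError("n11 cannot exceed either margin")
        if max(self.n1dot, self.ndot1) > self.ndotdot:
            raise ValueError("margins cannot exceed the total")
        if self.n1dot + self.ndot1 - self.n11 > self.ndotdot:
            raise ValueError("cell counts exceed the total")


def read_reports(path) -> list:
    """Read a long-format report file into one :class:`Report` per case.

    The file is tab-separated with columns ``case_id, drug, role, event_pt``;
    each row pairs one drug mention with one event mention of the same case.
    Duplicate rows collapse (set semantics).  Rows with missing fields or an
    unknown role are rejected with their file line numbers (warning).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"report file {path}: missing required columns {missing}")
    bad = df[REPORT_COLUMNS].isna().any(axis=1) | ~df["role"].isin(_VALID_ROLES)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        warnings.warn(
            f"report file {path}: rejected {bad.sum()} malformed rows "
            f"at lines {lines[:20]}{'...' if len(lines) > 20 else ''}"
        )
        df = df[~bad]
    reports = []
    for case_id, grp in df.groupby("case_id", sort=True):
        drugs = frozenset(zip(grp["drug"], grp["role"]))
        events = frozenset(grp["event_pt"])
        reports.append(Report(case_id=str(case_id), drugs=drugs, events=events))
    return reports


def write_reports(reports: Sequence[Report], path) -> None:
    """Write reports in the long cross format read back by :func:`read_reports`."""
    rows = []
    for r in sorted(reports, key=lambda r: r.case_id):
        for (drug, role), event in itertools.product(
            sorted(r.drugs), sorted(r.events)
        ):
            rows.append((r.case_id, drug, role, event))
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(
        Path(path), sep="\t", index=False
    )


def build_contingency(
    reports: Sequence[Report],
    drug: DrugClass,
    event: EventDefinition,
    suspect_only: bool = True,
) -> ContingencyTable:
    """Count cases into the 2x2 table for one drug class x event group.

    ``suspect_only`` restricts drug membership to suspect-role mentions,
    the conventional reading for signal detection.
    """
    if not reports:
        raise ValueError("empty report set")
    terms = event.all_terms()
    n11 = n1dot = ndot1 = 0
    for r in reports:
        has_drug = any(drug.matches(name) for name in r.drug_names(suspect_only))
        has_event = bool(terms & r.events)
        n1dot += has_drug
        ndot1 += has_event
        n11 += has_drug and has_event
    return ContingencyTable(n11, n1dot, ndot1, len(reports))


def enumerate_pairs(
    reports: Sequence[Report],
    drug_classes: Iterable[DrugClass],
    event_definitions: Iterable[EventDefinition],
    suspect_only: bool = True,
) -> list:
    """All (drug class, event group, table) combinations in input order."""
    return [
        (d, e, build_contingency(reports, d, e, suspect_only))
        for d in drug_classes
        for e in event_definitions
    ]
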