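"""Reading, joining and de-duplicating FAERS-style quarterly ASCII tables.

The public FAERS quarterly extracts ship five case-level tables (DEMO, DRUG,
REAC, THER, OUTC) as ``$``-delimited text with a header line, all keyed by
PRIMARYID (one row per report version) and, in DEMO, CASEID (one row per
safety case, possibly several versions).  This module parses that dialect,
collapses case versions to the current one, and joins the tables into
:class:`CaseReport` records that the rest of the pipeline consumes.

De-duplication follows the FDA-recommended rule: among reports sharing a
CASEID keep the one with the most recent FDA receipt date (FDA_DT), breaking
ties by the highest PRIMARYID.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "THER", "OUTC")

#: FAERS outcome codes: death, life-threatening, hospitalisation, disability,
#: congenital anomaly, required intervention, other serious.
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

AGE_FACTORS = {"DEC": 10.0, "YR": 1.0, "MON": 1 / 12, "WK": 1 / 52, "DY": 1 / 365.25}
WEIGHT_FACTORS = {"KG": 1.0, "KGS": 1.0, "LBS": 0.4536, "GMS": 0.001}

_WS = re.compile(r"\s+")


class FaersFormatError(ValueError):
    """Raised when a table file does not follow the FAERS ASCII dialect."""


# ---------------------------------------------------------------------------
# partial dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=False)
class PartialDate:
    """A FAERS calendar date with explicit precision.

    FAERS date fields may carry 8 digits (YYYYMMDD), 6 (YYYYMM), 4 (YYYY) or
    be blank/garbled.  Ordering between dates of different precision uses the
    earliest-possible-day completion; a date with precision ``none`` orders
    before every real date.
    """

    year: int | None = None
    month: int | None = None
    day: int | None = None
    precision: str = "none"  # day | month | year | none

    @property
    def ordering_key(self) -> date:
        if self.precision == "none":
            return date.min
        return date(self.year, self.month or 1, self.day or 1)

    def as_date(self) -> date | None:
        """Exact calendar day, or None unless precision is ``day``."""
        if self.precision != "day":
            return None
        return date(self.year, self.month, self.day)

    def __lt__(self, other: "PartialDate") -> bool:
        return self.ordering_key < other.ordering_key

    def __le__(self, other: "PartialDate") -> bool:
        return self.ordering_key <= other.ordering_key


def parse_partial_date(raw: str | None) -> PartialDate:
    """Parse a FAERS date string into a :class:`PartialDate`.

    Non-digit or out-of-range input yields precision ``none`` rather than an
    exception: spontaneous-report dates are frequently malformed and a bad
    date must never abort ingestion.
    """
    if raw is None:
        return PartialDate()
    raw = raw.strip()
    if not raw.isdigit():
        return PartialDate()
    try:
        if len(raw) == 8:
            d = date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
            return PartialDate(d.year, d.month, d.day, "day")
        if len(raw) == 6:
            d = date(int(raw[:4]), int(raw[4:6]), 1)
            return PartialDate(d.year, d.month, None, "month")
        if len(raw) == 4:
            return PartialDate(int(raw), None, None, "year")
    except ValueError:
        return PartialDate()
    return PartialDate()


# ---------------------------------------------------------------------------
# raw tables
# ---------------------------------------------------------------------------

@dataclass
class RawRecordSet:
    """One parsed FAERS table: a list of row dicts keyed by lower-cased column."""

    table_name: str
    rows: list[dict]
    n_skipped: int = 0

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def read_faers_table(path: str | Path, table_name: str) -> RawRecordSet:
    """Read one ``$``-delimited FAERS ASCII table.

    Empty fields become ``None``.  Rows whose field count disagrees with the
    header are skipped and counted in ``n_skipped``; a malformed header is a
    hard :class:`FaersFormatError` naming the file.
    """
    path = Path(path)
    table_name = table_name.upper()
    if table_name not in TABLE_NAMES:
        raise ValueError(f"unknown table name {table_name!r}")
    with open(path, encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline().rstrip("\r\n")
        if not header_line or "$" not in header_line and len(header_line.split()) > 1:
            raise FaersFormatError(f"{path}: malformed header line {header_line!r}")
        columns = [c.strip().lower() for c in header_line.split("$")]
        if any(not c for c in columns) or len(set(columns)) != len(columns):
            raise FaersFormatError(f"{path}: malformed header line {header_line!r}")
        rows: list[dict] = []
        n_skipped = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) != len(columns):
                n_skipped += 1
                logger.warning("%s:%d: expected %d fields, got %d; skipped",
                               path, lineno, len(columns), len(fields))
                continue
            rows.append({c: (v if v != "" else None) for c, v in zip(columns, fields)})
    return RawRecordSet(table_name=table_name, rows=rows, n_skipped=n_skipped)


def _primaryid_key(pid: str | None) -> tuple[int, str]:
    # numeric comparison when possible, lexicographic fallback
    s = "" if pid is None else str(pid)
    return (int(s), "") if s.isdigit() else (-1, s)


def deduplicate(demo: RawRecordSet) -> RawRecordSet:
    """Collapse DEMO to one row per CASEID.

    Keeps the row with the most recent FDA_DT; ties broken by the highest
    PRIMARYID.  An unparseable FDA_DT sorts below every dated version, so a
    dated report version always wins over an undated one.  Output rows are
    sorted by CASEID for determinism.  Idempotent.
    """
    best: dict[str, tuple] = {}
    n_bad_dates = 0
    for row in demo.rows:
        caseid = row.get("caseid")
        pdt = parse_partial_date(row.get("fda_dt"))
        if row.get("fda_dt") is not None and pdt.precision == "none":
            n_bad_dates += 1
        key = (pdt.ordering_key, _primaryid_key(row.get("primaryid")))
        if caseid not in best or key > best[caseid][0]:
            best[caseid] = (key, row)
    if n_bad_dates:
        logger.warning("deduplicate: %d rows with unparseable fda_dt ranked lowest", n_bad_dates)
    rows = [best[cid][1] for cid in sorted(best, key=lambda c: (c is None, str(c)))]
    return RawRecordSet(table_name=demo.table_name, rows=rows, n_skipped=demo.n_skipped)


# ---------------------------------------------------------------------------
# case assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugEntry:
    """One drug as reported in a case, with its suspicion role code."""

    drug_name: str
    role: str  # PS | SS | C | I
    route: str | None = None
    start_dt: PartialDate = field(default_factory=PartialDate)


@dataclass
class CaseReport:
    """A de-duplicated safety report joined across the five FAERS tables."""

    primaryid: str
    caseid: str
    fda_dt: PartialDate = field(default_factory=PartialDate)
    event_dt: PartialDate = field(default_factory=PartialDate)
    age_years: float | None = None
    sex: str = "unknown"  # F | M | unknown
    weight_kg: float | None = None
    reporter_occupation: str | None = None
    country: str | None = None
    outcomes: frozenset = frozenset()
    drugs: list = field(default_factory=list)
    reaction_pts: frozenset = frozenset()

    @property
    def serious(self) -> bool:
        """A case is serious iff it carries at least one outcome code."""
        return len(self.outcomes) > 0

    def drug_names(self, roles: Iterable[str] = ("PS",)) -> set[str]:
        roles = set(roles)
        return {d.drug_name for d in self.drugs if d.role in roles}


def normalize_drug_name(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Upper-case, collapse internal whitespace, then apply an optional
    user-supplied brand-to-generic synonym map (keys already normalized)."""
    norm = _WS.sub(" ", name.strip().upper())
    if synonyms:
        norm = synonyms.get(norm, norm)
    return norm


def convert_age_years(age: str | float | None, age_cod: str | None) -> float | None:
    """AGE + AGE_COD to years; unknown codes or implausible values (outside
    [0, 130] years) are treated as missing."""
    if age is None:
        return None
    try:
        value = float(age)
    except (TypeError, ValueError):
        return None
    factor = AGE_FACTORS.get((age_cod or "YR").upper())
    if factor is None:
        return None
    years = value * factor
    if not 0 <= years <= 130:
        return None
    return years


def convert_weight_kg(wt: str | float | None, wt_cod: str | None) -> float | None:
    """WT + WT_COD to kilograms; implausible values (outside (0, 700) kg)
    are treated as missing."""
    if wt is None:
        return None
    try:
        value = float(wt)
    except (TypeError, ValueError):
        return None
    factor = WEIGHT_FACTORS.get((wt_cod or "KG").upper())
    if factor is None:
        return None
    kg = value * factor
    if not 0 < kg < 700:
        return None
    return kg


def assemble_cases(
    demo: RawRecordSet,
    drug: RawRecordSet,
    reac: RawRecordSet,
    ther: RawRecordSet | None = None,
    outc: RawRecordSet | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> list[CaseReport]:
    """Join the five tables on PRIMARYID into :class:`CaseReport` records.

    ``demo`` must already be de-duplicated.  DRUG/REAC rows whose primaryid is
    absent from DEMO are dropped (count logged).  A drug listed k>1 times in
    one case with the same normalized name and role collapses to a single
    :class:`DrugEntry` keeping the earliest start date.  Cases ending up with
    no drugs or no reaction PTs after the join are dropped: a spontaneous
    report is only interpretable with at least one of each.
    """
    retained = {row.get("primaryid") for row in demo.rows}

    # start dates: THER keyed by primaryid + dsg_drug_seq
    starts: dict[tuple, PartialDate] = {}
    if ther is not None:
        for row in ther.rows:
            key = (row.get("primaryid"), row.get("dsg_drug_seq"))
            pdt = parse_partial_date(row.get("start_dt"))
            if key not in starts or pdt.ordering_key < starts[key].ordering_key:
                starts[key] = pdt

    drugs_by_pid: dict[str, dict[tuple, DrugEntry]] = {}
    n_orphan = 0
    for row in drug.rows:
        pid = row.get("primaryid")
        if pid not in retained:
            n_orphan += 1
            continue
        name = row.get("drugname") or row.get("drug_name")
        role = (row.get("role_cod") or "").upper()
        if not name or role not in {"PS", "SS", "C", "I"}:
            continue
        name = normalize_drug_name(name, synonyms)
        start = starts.get((pid, row.get("drug_seq")), PartialDate())
        entry = DrugEntry(drug_name=name, role=role, route=row.get("route"), start_dt=start)
        bucket = drugs_by_pid.setdefault(pid, {})
        prev = bucket.get((name, role))
        if prev is None:
            bucket[(name, role)] = entry
        else:
            # same drug+role reported repeatedly: keep the earliest dated start
            keep_new = (start.precision != "none"
                        and (prev.start_dt.precision == "none"
                             or start.ordering_key < prev.start_dt.ordering_key))
            if keep_new:
                bucket[(name, role)] = entry

    pts_by_pid: dict[str, set[str]] = {}
    for row in reac.rows:
        pid = row.get("primaryid")
        if pid not in retained:
            n_orphan += 1
            continue
        pt = row.get("pt")
        if pt:
            pts_by_pid.setdefault(pid, set()).add(pt.strip())

    outcomes_by_pid: dict[str, set[str]] = {}
    if outc is not None:
        for row in outc.rows:
            pid = row.get("primaryid")
            if pid not in retained:
                continue
            code = (row.get("outc_cod") or "").upper()
            if code in OUTCOME_CODES:
                outcomes_by_pid.setdefault(pid, set()).add(code)

    if n_orphan:
        logger.info("assemble_cases: dropped %d DRUG/REAC rows with no retained DEMO row", n_orphan)

    cases: list[CaseReport] = []
    n_empty = 0
    for row in demo.rows:
        pid = row.get("primaryid")
        entries = list(drugs_by_pid.get(pid, {}).values())
        pts = pts_by_pid.get(pid, set())
        if not entries or not pts:
            n_empty += 1
            continue
        sex = (row.get("sex") or "").upper()
        cases.append(CaseReport(
            primaryid=pid,
            caseid=row.get("caseid"),
            fda_dt=parse_partial_date(row.get("fda_dt")),
            event_dt=parse_partial_date(row.get("event_dt")),
            age_years=convert_age_years(row.get("age"), row.get("age_cod")),
            sex=sex if sex in {"F", "M"} else "unknown",
            weight_kg=convert_weight_kg(row.get("wt"), row.get("wt_cod")),
            reporter_occupation=row.get("occp_cod"),
            country=row.get("occr_country") or row.get("reporter_country"),
            outcomes=frozenset(outcomes_by_pid.get(pid, set())),
            drugs=sorted(entries, key=lambda e: (e.role, e.drug_name)),
            reaction_pts=frozenset(pts),
        ))
    if n_empty:
        logger.info("assemble_cases: dropped %d cases with no drugs or no reactions", n_empty)
    return cases
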