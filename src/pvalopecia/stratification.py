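"""Descriptive summaries, subgroup signal analyses, risk tiers and label
cross-checks.

Age bands follow the <18 / 18-44 / 45-64 / >=65 grouping (left-closed,
right-open except the top band).  Subgroup 2x2 tables are rebuilt from
stratum members only, and p-values within a stratum carry a Bonferroni
adjustment whose family is the number of drugs evaluated in that stratum.
Risk tiers cut on the BCPNN credibility bound: high IC025 > 3, medium
1.5 < IC025 <= 3, low IC025 <= 1.5.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .case_definition import DrugCaseIndex, build_drug_case_index
from .disproportionality import MgpsPrior, SignalThresholds, DEFAULT_THRESHOLDS, signal_table
from .faers_io import CaseReport

logger = logging.getLogger(__name__)

AGE_BANDS = ("<18", "18-44", "45-64", ">=65")

#: reporting-year bins used in baseline tables (inclusive year ranges)
DEFAULT_YEAR_BINS = (("2004Q1-2010Q4", 2004, 2010), ("2011Q1-2015Q4", 2011, 2015),
                     ("2016Q1-2020Q4", 2016, 2020), ("2021Q1-2024Q4", 2021, 2024))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for presentation (banker's rounding would
    disagree with hand-computed percentages at the .x5 boundary)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return math.nan
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, total: float, ndigits: int = 2) -> float:
    if total == 0:
        return math.nan
    return round_half_up(100.0 * count / total, ndigits)


def age_band(age_years: float | None) -> str | None:
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return None
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18-44"
    if age_years < 65:
        return "45-64"
    return ">=65"


@dataclass(frozen=True)
class StratumSpec:
    """One subgroup: an age band, a sex, a drug category, or a combination
    ('any' leaves the axis unrestricted).  Age/sex restrict which *cases*
    enter the stratum (cases missing the field fall outside); category
    restricts which *drugs* are evaluated and needs a drug->category map."""

    age_band: str = "any"
    sex: str = "any"
    category: str = "any"
    label: str = ""

    def name(self) -> str:
        if self.label:
            return self.label
        parts = []
        if self.age_band != "any":
            parts.append(f"age {self.age_band}")
        if self.sex != "any":
            parts.append(f"sex {self.sex}")
        if self.category != "any":
            parts.append(f"category {self.category}")
        return ", ".join(parts) or "all"

    def contains(self, case: CaseReport) -> bool:
        if self.age_band != "any" and age_band(case.age_years) != self.age_band:
            return False
        if self.sex != "any" and case.sex != self.sex:
            return False
        return True


# ---------------------------------------------------------------------------
# descriptive baseline
# ---------------------------------------------------------------------------

def _year_bin(year: int | None) -> str | None:
    if year is None:
        return None
    for label, lo, hi in DEFAULT_YEAR_BINS:
        if lo <= year <= hi:
            return label
    return None


def baseline_summary(cases: Sequence[CaseReport], event_ids: set | None = None) -> pd.DataFrame:
    """Table-1-style summary of the event cases: counts and percentages for
    sex, reporting year, region, reporter occupation, severity and outcome
    codes, plus mean/SD/median/IQR for age and weight.

    Percentages are over the event-case total and rounded half-up to two
    decimals; raw counts are retained alongside.
    """
    if event_ids is not None:
        cases = [c for c in cases if c.primaryid in event_ids]
    total = len(cases)
    rows: list[dict] = []

    def add_block(block: str, counts: Mapping[str, int]):
        for level, n in counts.items():
            rows.append({"block": block, "level": level, "count": n,
                         "percent": percentage(n, total)})

    sex_counts = {"F": 0, "M": 0, "unknown": 0}
    year_counts: dict[str, int] = {label: 0 for label, *_ in DEFAULT_YEAR_BINS}
    region_counts: dict[str, int] = {}
    occ_counts: dict[str, int] = {}
    outcome_counts: dict[str, int] = {}
    serious = 0
    ages, weights = [], []
    for c in cases:
        sex_counts[c.sex] += 1
        yb = _year_bin(c.fda_dt.year)
        if yb:
            year_counts[yb] += 1
        if c.country:
            region_counts[c.country] = region_counts.get(c.country, 0) + 1
        occ = c.reporter_occupation or "unknown"
        occ_counts[occ] = occ_counts.get(occ, 0) + 1
        if c.serious:
            serious += 1
        for code in c.outcomes:
            outcome_counts[code] = outcome_counts.get(code, 0) + 1
        if c.age_years is not None:
            ages.append(c.age_years)
        if c.weight_kg is not None:
            weights.append(c.weight_kg)

    add_block("sex", sex_counts)
    add_block("reporting_year", year_counts)
    add_block("region", dict(sorted(region_counts.items(), key=lambda kv: -kv[1])))
    add_block("occupation", dict(sorted(occ_counts.items(), key=lambda kv: -kv[1])))
    add_block("severity", {"serious": serious, "non-serious": total - serious})
    add_block("outcome", dict(sorted(outcome_counts.items())))

    for name, values in (("age_years", ages), ("weight_kg", weights)):
        if values:
            arr = np.asarray(values, dtype=float)
            rows.append({"block": name, "level": "mean", "count": len(arr),
                         "percent": math.nan, "value": float(arr.mean())})
            rows.append({"block": name, "level": "sd", "count": len(arr),
                         "percent": math.nan, "value": float(arr.std(ddof=1)) if len(arr) > 1 else math.nan})
            q1, med, q3 = np.percentile(arr, [25, 50, 75])
            for lv, v in (("median", med), ("q1", q1), ("q3", q3)):
                rows.append({"block": name, "level": lv, "count": len(arr),
                             "percent": math.nan, "value": float(v)})
        rows.append({"block": name, "level": "missing", "count": total - len(values),
                     "percent": percentage(total - len(values), total)})
    return pd.DataFrame(rows)


def category_shares(counts: Mapping[str, int], total: int | None = None,
                    ndigits: int = 1) -> dict:
    """Percentage share per category, half-up rounded; denominator defaults
    to the sum of the counts."""
    denom = sum(counts.values()) if total is None else total
    return {k: percentage(v, denom, ndigits) for k, v in counts.items()}


# ---------------------------------------------------------------------------
# subgroup signals
# ---------------------------------------------------------------------------

def stratified_signals(
    cases: Sequence[CaseReport],
    event_ids: set,
    strata: Iterable[StratumSpec],
    role_filter: Iterable[str] = ("PS",),
    prior: MgpsPrior | None = None,
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
    min_cases: int = 1,
    alpha: float = 0.05,
    drug_categories: Mapping[str, str] | None = None,
) -> dict:
    """Per-stratum signal tables with stratum-restricted denominators.

    For each stratum the population, event set and per-drug sets are rebuilt
    from stratum members only, then all four statistics run unchanged.  A
    category stratum instead keeps all cases but evaluates only the drugs
    mapped to that category (``drug_categories``, upper-cased keys).  The
    Bonferroni family is the number of drugs evaluated within the stratum;
    the ``lost_significance`` column marks drugs whose raw Fisher p is below
    ``alpha`` but whose adjusted p is not.

    Pass the whole-database MGPS ``prior`` for narrow strata: the
    empirical-Bayes step needs many drug-event pairs, and a stratum with a
    handful of drugs cannot support its own fit.
    """
    out: dict[str, pd.DataFrame] = {}
    for spec in strata:
        members = [c for c in cases if spec.contains(c)]
        idx = build_drug_case_index(members, event_ids, role_filter)
        if spec.category != "any":
            if drug_categories is None:
                raise ValueError("category stratum needs a drug_categories map")
            keep = {d: s for d, s in idx.drug_cases.items()
                    if drug_categories.get(d.upper()) == spec.category}
            idx = DrugCaseIndex(drug_cases=keep, event_cases=idx.event_cases,
                                all_cases=idx.all_cases)
        if not idx.event_cases or not idx.drug_cases:
            logger.info("stratum %s: no event cases or drugs; skipped", spec.name())
            out[spec.name()] = pd.DataFrame()
            continue
        df = signal_table(idx, prior=prior, thresholds=thresholds, min_cases=min_cases)
        df.insert(0, "stratum", spec.name())
        df["lost_significance"] = (df["fisher_p"] < alpha) & (df["p_adjusted"] >= alpha)
        out[spec.name()] = df
    return out


# ---------------------------------------------------------------------------
# risk tiers
# ---------------------------------------------------------------------------

def risk_tier(ic025: float) -> str | None:
    """high: IC025 > 3; medium: 1.5 < IC025 <= 3; low: IC025 <= 1.5 (boundary
    values fall in the lower tier, matching the inclusive upper bounds)."""
    if ic025 is None or (isinstance(ic025, float) and math.isnan(ic025)):
        return None
    if ic025 > 3:
        return "high"
    if ic025 > 1.5:
        return "medium"
    return "low"


def classify_risk_tier(ic025_by_drug: Mapping[str, float]) -> tuple[dict, dict]:
    """Tier per drug plus tier counts; drugs without an IC025 are left
    unclassified (logged)."""
    tiers: dict[str, str] = {}
    counts = {"high": 0, "medium": 0, "low": 0}
    for drug, value in ic025_by_drug.items():
        tier = risk_tier(value)
        if tier is None:
            logger.warning("classify_risk_tier: %s has no IC025; unclassified", drug)
            continue
        tiers[drug] = tier
        counts[tier] += 1
    return tiers, counts


# ---------------------------------------------------------------------------
# PT-level distribution
# ---------------------------------------------------------------------------

def pt_level_distribution(
    cases: Sequence[CaseReport],
    pts: Iterable[str],
    role_filter: Iterable[str] = ("PS",),
    top_k: int = 10,
) -> pd.DataFrame:
    """For each preferred term, the share of its cases attributable to each
    suspect drug (top-k rows per PT).  A case with several suspect drugs
    contributes to each, so shares per PT can sum below or at 100%."""
    roles = set(role_filter)
    keys = {pt.casefold(): pt for pt in pts}
    rows = []
    for key, label in keys.items():
        pt_cases = [c for c in cases if any(p.casefold() == key for p in c.reaction_pts)]
        denom = len(pt_cases)
        if denom == 0:
            continue
        counts: dict[str, int] = {}
        for c in pt_cases:
            for d in c.drug_names(roles):
                counts[d] = counts.get(d, 0) + 1
        top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        for rank, (drug, n) in enumerate(top, start=1):
            rows.append({"pt": label, "rank": rank, "drug_name": drug, "n_cases": n,
                         "pt_total": denom, "share_pct": percentage(n, denom)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# label cross-check
# ---------------------------------------------------------------------------

def load_drug_categories(path: str | Path, drug_column: str = "drug_name",
                         category_column: str = "category") -> dict:
    """Drug -> therapeutic-category map from a two-column CSV (keys
    upper-cased to match normalized drug names)."""
    out = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[row[drug_column].strip().upper()] = row[category_column].strip()
    return out


@dataclass(frozen=True)
class LabelAnnotation:
    drug_name: str
    documented: bool


def load_label_annotations(path: str | Path) -> list:
    truthy = {"1", "true", "yes", "y", "t"}
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(LabelAnnotation(
                drug_name=row["drug_name"].strip(),
                documented=row["documented"].strip().casefold() in truthy,
            ))
    return out


def label_crosscheck(drug_names: Iterable[str], annotations: Iterable[LabelAnnotation]) -> dict:
    """Partition signal-positive drugs into label-documented vs not, with
    percentages over the positive-drug total (half-up, one decimal).  Drugs
    lacking an annotation are counted 'unknown' and logged."""
    ann = {a.drug_name.upper(): a.documented for a in annotations}
    documented, undocumented, unknown = [], [], []
    for drug in drug_names:
        status = ann.get(drug.upper())
        if status is None:
            logger.warning("label_crosscheck: no annotation for %s", drug)
            unknown.append(drug)
        elif status:
            documented.append(drug)
        else:
            undocumented.append(drug)
    total = len(documented) + len(undocumented) + len(unknown)
    return {
        "documented": sorted(documented),
        "undocumented": sorted(undocumented),
        "unknown": sorted(unknown),
        "n_total": total,
        "documented_pct": percentage(len(documented), total, 1),
        "undocumented_pct": percentage(len(undocumented), total, 1),
    }
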