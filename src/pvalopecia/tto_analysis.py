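"""Time-to-onset (TTO) analysis: latency extraction, Weibull fits, and
group comparisons.

TTO is the whole-day difference between the event date and the earliest
Primary-Suspect start date of the drug in a case.  Only day-precision date
pairs qualify; negative intervals are excluded.  Latency distributions are
summarised by median/quartiles and a 30-day-binned histogram, modelled with
a two-parameter Weibull (shape beta, scale eta in days) whose shape
separates early-failure hazards (beta < 1, acute cytotoxic hair loss) from
wear-out hazards (beta > 1, delayed cycle-shift shedding), and compared
between groups with the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from datetime import date as date_type

import numpy as np
import pandas as pd
from lifelines import WeibullFitter
from scipy import stats

from .faers_io import CaseReport

logger = logging.getLogger(__name__)

#: 30-day steps to 240 days, then 240-360 and beyond; bins are [lo, hi)
DEFAULT_BIN_EDGES = (0, 30, 60, 90, 120, 150, 180, 210, 240, 360, math.inf)

MIN_WEIBULL_N = 10


@dataclass(frozen=True)
class TtoRecord:
    primaryid: str
    drug_name: str
    days: int

    def __post_init__(self):
        if self.days < 0:
            raise ValueError("days must be non-negative")


@dataclass(frozen=True)
class WeibullFit:
    """Maximum-likelihood Weibull parameters with 95% CIs.

    ``shape`` is beta (dimensionless), ``scale`` eta in days; the median
    latency follows the closed form eta * ln(2)^(1/beta).
    """

    shape: float
    scale: float
    ci_shape: tuple
    ci_scale: tuple
    n: int
    converged: bool = True

    @property
    def median_days(self) -> float:
        return self.scale * math.log(2) ** (1 / self.shape)


class WeibullFitError(RuntimeError):
    pass


def extract_tto(
    cases: Sequence[CaseReport],
    drug_name: str,
    roles: Iterable[str] = ("PS",),
) -> list:
    """TTO records for one drug.

    Uses the earliest day-precision start date among the drug's qualifying
    role entries and the case's day-precision event date; cases with missing
    or partial dates, or event before start, are excluded (counts logged).
    Output is sorted by primaryid, so it is invariant to case ordering.
    """
    roles = set(roles)
    records = []
    n_excluded = 0
    for case in cases:
        starts = [d.start_dt.as_date() for d in case.drugs
                  if d.drug_name == drug_name and d.role in roles
                  and d.start_dt.precision == "day"]
        event = case.event_dt.as_date()
        if not starts or event is None:
            n_excluded += 1
            continue
        days = (event - min(starts)).days
        if days < 0:
            n_excluded += 1
            continue
        records.append(TtoRecord(case.primaryid, drug_name, days))
    if n_excluded:
        logger.debug("extract_tto(%s): %d cases without a usable date pair", drug_name, n_excluded)
    return sorted(records, key=lambda r: str(r.primaryid))


def _median_of(sorted_vals: Sequence[float]) -> float:
    n = len(sorted_vals)
    mid = n // 2
    return float(sorted_vals[mid]) if n % 2 else (sorted_vals[mid - 1] + sorted_vals[mid]) / 2.0


def quartiles(values: Sequence[float]) -> tuple:
    """(Q1, median, Q3) by the median-of-halves convention: the halves
    exclude the middle observation when n is odd."""
    vals = sorted(float(v) for v in values)
    n = len(vals)
    if n == 0:
        raise ValueError("no values")
    if n == 1:
        return vals[0], vals[0], vals[0]
    med = _median_of(vals)
    half = n // 2
    return _median_of(vals[:half]), med, _median_of(vals[n - half:])


def summarize_tto(
    records: Sequence[TtoRecord],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> dict:
    """Median/Q1/Q3 plus a binned histogram over half-open [lo, hi) bins.

    Returns an empty summary (n=0) for empty input.
    """
    days = [r.days for r in records]
    n = len(days)
    if n == 0:
        return {"n": 0, "median": math.nan, "q1": math.nan, "q3": math.nan,
                "histogram": [], "mean": math.nan}
    q1, med, q3 = quartiles(days)
    edges = list(bin_edges)
    counts, _ = np.histogram(days, bins=[e if math.isfinite(e) else np.inf for e in edges])
    hist = []
    for lo, hi, cnt in zip(edges[:-1], edges[1:], counts):
        label = f"{lo:g}-{hi:g}" if math.isfinite(hi) else f">{lo:g}"
        hist.append({"bin": label, "lo": lo, "hi": hi, "count": int(cnt),
                     "share_pct": 100.0 * cnt / n})
    return {"n": n, "median": med, "q1": q1, "q3": q3,
            "mean": float(np.mean(days)), "histogram": hist}


def fit_weibull(
    records: Sequence[TtoRecord] | Sequence[float],
    zero_shift: float = 0.5,
) -> WeibullFit:
    """Fit shape/scale by maximum likelihood (no censoring: spontaneous
    reports carry no at-risk denominators).

    Zero-day onsets are shifted by ``zero_shift`` days because the Weibull
    support is the positive reals; the shift is half the one-day recording
    resolution.  Requires at least 10 records with >= 2 distinct values.
    """
    days = np.asarray([r.days if isinstance(r, TtoRecord) else r for r in records], dtype=float)
    if len(days) < MIN_WEIBULL_N:
        raise WeibullFitError(f"need >= {MIN_WEIBULL_N} records, got {len(days)}")
    days = np.where(days <= 0, zero_shift, days)
    if len(np.unique(days)) < 2:
        raise WeibullFitError("all latencies identical; shape is unidentifiable")
    wf = WeibullFitter()
    wf.fit(days, event_observed=np.ones_like(days))
    ci = wf.summary  # per-parameter MLE table with normal-approximation CIs
    lo, hi = "coef lower 95%", "coef upper 95%"
    # lifelines: S(t) = exp(-(t/lambda_)^rho_), so lambda_ = eta, rho_ = beta
    return WeibullFit(
        shape=float(wf.rho_),
        scale=float(wf.lambda_),
        ci_shape=(float(ci.loc["rho_", lo]), float(ci.loc["rho_", hi])),
        ci_scale=(float(ci.loc["lambda_", lo]), float(ci.loc["lambda_", hi])),
        n=len(days),
    )


def compare_tto_groups(
    records_g1: Sequence[TtoRecord] | Sequence[float],
    records_g2: Sequence[TtoRecord] | Sequence[float],
    exact_max_n: int = 12,
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two latency samples.

    Exact enumeration when the pooled size allows it and there are no ties;
    otherwise the tie-corrected normal approximation.  Also reports group
    means and medians.
    """
    g1 = np.asarray([r.days if isinstance(r, TtoRecord) else r for r in records_g1], dtype=float)
    g2 = np.asarray([r.days if isinstance(r, TtoRecord) else r for r in records_g2], dtype=float)
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": method,
        "mean_g1": float(g1.mean()), "mean_g2": float(g2.mean()),
        "median_g1": float(np.median(g1)), "median_g2": float(np.median(g2)),
        "n_g1": len(g1), "n_g2": len(g2),
    }


def per_drug_tto_table(
    cases: Sequence[CaseReport],
    drug_names: Iterable[str],
    min_fit_n: int = MIN_WEIBULL_N,
) -> pd.DataFrame:
    """One row per drug: n, median/Q1/Q3, and Weibull shape/scale with CIs
    when the per-drug sample reaches the fit floor (otherwise NaN, the
    summary columns are still emitted)."""
    wanted = set(drug_names)
    by_drug: dict[str, list] = {d: [] for d in wanted}
    # single pass over the case list; equivalent to extract_tto per drug
    for case in cases:
        event = case.event_dt.as_date()
        if event is None:
            continue
        starts: dict[str, date_type] = {}
        for entry in case.drugs:
            if (entry.role == "PS" and entry.drug_name in wanted
                    and entry.start_dt.precision == "day"):
                start = entry.start_dt.as_date()
                prev = starts.get(entry.drug_name)
                if prev is None or start < prev:
                    starts[entry.drug_name] = start
        for name, start in starts.items():
            days = (event - start).days
            if days >= 0:
                by_drug[name].append(TtoRecord(case.primaryid, name, days))

    rows = []
    for drug in drug_names:
        recs = by_drug.get(drug, [])
        if not recs:
            continue
        s = summarize_tto(recs)
        row = {"drug_name": drug, "n": s["n"], "median_days": s["median"],
               "q1_days": s["q1"], "q3_days": s["q3"], "mean_days": s["mean"],
               "weibull_shape": math.nan, "weibull_scale": math.nan,
               "shape_lo": math.nan, "shape_hi": math.nan,
               "scale_lo": math.nan, "scale_hi": math.nan}
        if s["n"] >= min_fit_n:
            try:
                fit = fit_weibull(recs)
                row.update({"weibull_shape": fit.shape, "weibull_scale": fit.scale,
                            "shape_lo": fit.ci_shape[0], "shape_hi": fit.ci_shape[1],
                            "scale_lo": fit.ci_scale[0], "scale_hi": fit.ci_scale[1]})
            except WeibullFitError as exc:
                logger.info("per_drug_tto_table(%s): %s", drug, exc)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("median_days", ascending=False, ignore_index=True) \
        if rows else pd.DataFrame()
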