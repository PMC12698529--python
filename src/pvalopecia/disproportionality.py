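"""Disproportionality statistics on drug-event 2x2 tables.

For one drug D and one event E over N de-duplicated cases the table is

    a = cases with D and E        b = cases with D, other events
    c = cases with E, other drugs d = everything else

Four statistics are computed per table, each with its conventional
signal-positivity criterion, and a drug is declared a signal only when all
four criteria hold simultaneously (the joint rule trades sensitivity for
specificity):

* ROR  — reporting odds ratio ad/bc with the Woolf log-normal 95% CI;
  positive when a >= 3 and the lower bound exceeds 1.
* PRR  — proportional reporting ratio [a/(a+b)] / [c/(c+d)] with the Pearson
  chi-square of the table; positive when a >= 3, PRR >= 2 and chi2 >= 4.
* IC   — BCPNN information component, a shrunk log2 observed-to-expected
  ratio with the Noren closed-form 2.5th-percentile bound IC025; positive
  when IC025 > 0.
* EBGM — DuMouchel's empirical-Bayes geometric mean under a two-gamma
  mixture prior fitted to the whole database by maximum marginal likelihood;
  positive when the 5th posterior percentile EBGM05 exceeds 2.

Undefined statistics (zero cells without continuity correction) are reported
as NaN markers, never exceptions, and count as failed flags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .case_definition import DrugCaseIndex

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d cells of a drug-event 2x2 over de-duplicated cases."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError(f"cells must be non-negative integers, got {self}")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected a under row/column independence: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def corrected(self, pseudo: float = 0.5) -> tuple:
        return (self.a + pseudo, self.b + pseudo, self.c + pseudo, self.d + pseudo)


def build_contingency(index: DrugCaseIndex, drug_name: str) -> ContingencyTable:
    """2x2 cells for one drug from the case index; the counting unit is the
    de-duplicated case."""
    if drug_name not in index.drug_cases:
        raise KeyError(f"drug {drug_name!r} not indexed")
    drug = index.drug_cases[drug_name]
    event = index.event_cases
    a = len(drug & event)
    b = len(drug) - a
    c = len(event) - a
    d = len(index.all_cases) - a - b - c
    return ContingencyTable(a, b, c, d)


class RorResult(NamedTuple):
    ror: float
    lo: float
    hi: float


class PrrResult(NamedTuple):
    prr: float
    chi2: float


class IcResult(NamedTuple):
    ic: float
    ic025: float


class EbgmResult(NamedTuple):
    ebgm: float
    ebgm05: float


def compute_ror(t: ContingencyTable, z: float = Z95, haldane: bool = False) -> RorResult:
    """Reporting odds ratio ad/bc with the Woolf interval
    exp(ln ROR +/- z*sqrt(1/a+1/b+1/c+1/d)).

    With a zero cell and ``haldane`` off the result is the NaN marker; with
    ``haldane`` on, 0.5 is added to every cell first.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if haldane:
        a, b, c, d = t.corrected()
    if min(a, b, c, d) == 0:
        return RorResult(math.nan, math.nan, math.nan)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorResult(ror, ror * math.exp(-z * se), ror * math.exp(z * se))


def compute_prr(t: ContingencyTable, yates: bool = False, haldane: bool = False) -> PrrResult:
    """Proportional reporting ratio and the 2x2 chi-square.

    chi2 is the Pearson statistic N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d));
    ``yates`` applies the continuity correction (|ad-bc| reduced by N/2).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if haldane:
        a, b, c, d = t.corrected()
    n = a + b + c + d
    if a + b == 0 or c + d == 0 or c == 0 or a + c == 0 or b + d == 0:
        return PrrResult(math.nan, math.nan)
    prr = (a / (a + b)) / (c / (c + d))
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    chi2 = n * diff * diff / ((a + b) * (c + d) * (a + c) * (b + d))
    return PrrResult(prr, chi2)


def compute_ic(t: ContingencyTable, shrunk: bool = True) -> IcResult:
    """BCPNN information component with the Noren credibility bound.

    IC = log2((a + 1/2) / (E + 1/2)) with E = (a+b)(a+c)/N; the 2.5th
    percentile is the closed-form approximation
    IC025 = IC - 3.3(a+1/2)^(-1/2) - 2(a+1/2)^(-3/2), which is strictly
    below IC for every table.  ``shrunk=False`` exposes the raw
    log2 observed-to-expected ratio (NaN when a = 0), sharing the same bound.
    """
    e = t.expected
    ic = (math.log2((t.a + 0.5) / (e + 0.5)) if shrunk
          else (math.log2(t.a / e) if t.a > 0 and e > 0 else math.nan))
    half = t.a + 0.5
    ic025 = ic - 3.3 * half ** -0.5 - 2.0 * half ** -1.5
    return IcResult(ic, ic025)


def compute_ic_mc(t: ContingencyTable, n_samples: int = 100_000,
                  seed: int = 0) -> IcResult:
    """Monte-Carlo variant of the information component interval.

    Draws the shrunk observed-to-expected ratio from its
    Gamma(a + 1/2, E + 1/2) posterior (whose mean reproduces the closed-form
    point estimate) and takes the empirical 2.5th percentile of log2 draws.
    Deterministic under ``seed``; the closed-form Noren bound remains the
    default because it needs no sampling.
    """
    e = t.expected
    rng = np.random.default_rng(seed)
    draws = rng.gamma(t.a + 0.5, 1.0 / (e + 0.5), size=n_samples)
    ic = math.log2((t.a + 0.5) / (e + 0.5))
    ic025 = float(np.log2(np.quantile(draws, 0.025)))
    return IcResult(ic, ic025)


# ---------------------------------------------------------------------------
# MGPS / EBGM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MgpsPrior:
    """DuMouchel's five hyperparameters: lambda ~ p*Gamma(a1,b1) + (1-p)*Gamma(a2,b2)
    (shape/rate parameterisation) for the Poisson rate ratio lambda = mu/E."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mix_p: float
    loglik: float = math.nan

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 < self.mix_p < 1:
            raise ValueError("mix_p must lie in (0,1)")


class MgpsFitError(RuntimeError):
    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


def _mixture_nll(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    """Negative log marginal likelihood: a_i ~ mixture of negative binomials
    (the gamma-Poisson marginal with size alpha_j, prob beta_j/(beta_j+E_i))."""
    a1, b1, a2, b2 = np.exp(theta[:4])
    p = special.expit(theta[4])
    lp1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    lp2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    ll = special.logsumexp(
        np.stack([lp1 + math.log(p), lp2 + math.log1p(-p)]), axis=0)
    return -float(np.sum(ll))


#: classic DuMouchel starting values for (alpha1, beta1, alpha2, beta2, p)
DEFAULT_MGPS_START = (0.2, 0.1, 2.0, 4.0, 1 / 3)


def fit_mgps_prior(
    tables: Sequence[ContingencyTable],
    n_starts: int = 6,
    seed: int = 0,
) -> MgpsPrior:
    """Fit the two-gamma mixture prior by maximum marginal likelihood.

    Each table contributes its observed count ``a`` and independence-expected
    count ``E``.  Optimisation runs L-BFGS-B on log/logit-transformed
    hyperparameters from the classic DuMouchel start plus seeded random
    perturbations, returning the best optimum found.  At least two tables are
    required (>= 50 recommended for a stable prior).
    """
    if len(tables) < 2:
        raise MgpsFitError(f"need >= 2 tables to fit a prior, got {len(tables)}")
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected for t in tables], dtype=float)
    if np.any(e <= 0):
        raise MgpsFitError("every table must have positive expected count")

    rng = np.random.default_rng(seed)
    base = np.array([*np.log(DEFAULT_MGPS_START[:4]), special.logit(DEFAULT_MGPS_START[4])])
    starts = [base] + [base + rng.normal(scale=1.0, size=5) for _ in range(n_starts - 1)]

    best = None
    for theta0 in starts:
        res = optimize.minimize(
            _mixture_nll, theta0, args=(a, e), method="L-BFGS-B",
            bounds=[(-10, 10)] * 4 + [(-8, 8)],
        )
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise MgpsFitError("all optimisation starts failed")
    a1, b1, a2, b2 = np.exp(best.x[:4])
    p = float(special.expit(best.x[4]))
    prior = MgpsPrior(float(a1), float(b1), float(a2), float(b2), p, loglik=-float(best.fun))
    if not best.success:
        logger.warning("fit_mgps_prior: optimiser flagged non-convergence; best ll=%.3f", prior.loglik)
    return prior


def _posterior_mixture(a: float, e: float, prior: MgpsPrior):
    """Posterior of lambda given a: two-gamma mixture with updated shapes,
    rates and evidence-weighted mixing probabilities."""
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    log_ev = np.array([
        math.log(prior.mix_p) + stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e)),
        math.log1p(-prior.mix_p) + stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e)),
    ])
    w = np.exp(log_ev - special.logsumexp(log_ev))
    return shapes, rates, w


def compute_ebgm(t: ContingencyTable, prior: MgpsPrior) -> EbgmResult:
    """Posterior geometric mean exp(E[ln lambda | a]) and its 5th percentile.

    The posterior is an exact two-gamma mixture, so E[ln lambda] is a
    weighted sum of digamma(shape) - ln(rate); the percentile is found by
    bisection on the mixture CDF.
    """
    e = t.expected
    if e <= 0:
        return EbgmResult(math.nan, math.nan)
    shapes, rates, w = _posterior_mixture(t.a, e, prior)
    ebgm = math.exp(float(np.sum(w * (special.digamma(shapes) - np.log(rates)))))

    def cdf(x):
        return float(np.sum(w * stats.gamma.cdf(x, shapes, scale=1 / rates)))

    # bracket from 0 (cdf exactly 0 there) so the root-find cannot lose the
    # quantile when a near-degenerate component piles mass at the origin
    hi = float(max(stats.gamma.ppf(0.9999, shapes, scale=1 / rates))) * 1.01 + 1e-9
    ebgm05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, 0.0, hi))
    return EbgmResult(ebgm, ebgm05)


# ---------------------------------------------------------------------------
# joint rule + volcano
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalThresholds:
    """Positivity criteria; all configurable, defaults are the conventional
    FAERS screening values."""

    min_a: int = 3
    ror_lo_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0


DEFAULT_THRESHOLDS = SignalThresholds()


@dataclass
class SignalResult:
    """All four statistics for one drug with per-method flags and the joint
    all-four-positive verdict."""

    drug_name: str
    table: ContingencyTable
    ror: float = math.nan
    ror_lo: float = math.nan
    ror_hi: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    fisher_p: float = math.nan
    p_adjusted: float = math.nan
    flags: dict = field(default_factory=dict)
    positive: bool = False


def evaluate_signal(
    drug_name: str,
    t: ContingencyTable,
    ror: RorResult,
    prr: PrrResult,
    ic: IcResult,
    ebgm: EbgmResult,
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
) -> SignalResult:
    """Apply the per-method criteria and the joint rule.

    An undefined (NaN) statistic fails its flag; the drug is positive only
    when all four flags hold.
    """
    th = thresholds
    flags = {
        "ror_pos": bool(t.a >= th.min_a and ror.lo > th.ror_lo_gt),
        "prr_pos": bool(t.a >= th.min_a and prr.prr >= th.prr_min and prr.chi2 >= th.chi2_min),
        "bcpnn_pos": bool(ic.ic025 > th.ic025_gt),
        "mgps_pos": bool(ebgm.ebgm05 > th.ebgm05_gt),
    }
    for name, ok in flags.items():
        if not ok and t.a >= th.min_a:
            logger.debug("%s: flag %s false", drug_name, name)
    return SignalResult(
        drug_name=drug_name, table=t,
        ror=ror.ror, ror_lo=ror.lo, ror_hi=ror.hi,
        prr=prr.prr, chi2=prr.chi2,
        ic=ic.ic, ic025=ic.ic025,
        ebgm=ebgm.ebgm, ebgm05=ebgm.ebgm05,
        flags=flags, positive=all(flags.values()),
    )


def fisher_volcano(tables: Sequence[ContingencyTable], alpha: float = 0.05) -> list:
    """Two-sided Fisher exact p per table with Bonferroni adjustment over the
    family of tested drugs, plus ln(ROR) for the volcano x-axis (Haldane
    correction applied only when a cell is zero, NaN-free axis)."""
    m = len(tables)
    if m == 0:
        raise ValueError("no tables supplied")
    out = []
    for t in tables:
        _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
        a, b, c, d = (t.corrected() if min(t.a, t.b, t.c, t.d) == 0
                      else (t.a, t.b, t.c, t.d))
        out.append((float(p), min(1.0, m * float(p)), math.log((a * d) / (b * c))))
    return out


def signal_table(
    index: DrugCaseIndex,
    prior: MgpsPrior | None = None,
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
    min_cases: int = 1,
    mgps_seed: int = 0,
    simplified: bool = False,
) -> pd.DataFrame:
    """Run all four methods over every indexed drug and return a tidy frame,
    one row per drug, including Fisher/Bonferroni columns.

    When no prior is supplied one is fitted across all drug tables (the
    empirical-Bayes step needs the whole database, not a single pair).
    ``simplified`` adds a ``log2_ebgm`` column so the Bayesian columns can be
    read side by side on the same log2 scale as the information component.
    """
    drugs = [d for d in index.drugs() if len(index.drug_cases[d]) >= min_cases]
    tables = [build_contingency(index, d) for d in drugs]
    if prior is None:
        prior = fit_mgps_prior(tables, seed=mgps_seed)
    volcano = fisher_volcano(tables)
    rows = []
    for drug, t, (p, p_adj, log_ror) in zip(drugs, tables, volcano):
        res = evaluate_signal(
            drug, t,
            compute_ror(t), compute_prr(t), compute_ic(t), compute_ebgm(t, prior),
            thresholds,
        )
        res.fisher_p, res.p_adjusted = p, p_adj
        rows.append({
            "drug_name": drug, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": res.ror, "ror_lo": res.ror_lo, "ror_hi": res.ror_hi,
            "prr": res.prr, "chi2": res.chi2,
            "ic": res.ic, "ic025": res.ic025,
            "ebgm": res.ebgm, "ebgm05": res.ebgm05,
            "fisher_p": p, "p_adjusted": p_adj, "log_ror": log_ror,
            **res.flags, "positive": res.positive,
        })
    df = pd.DataFrame(rows)
    if simplified and not df.empty:
        df["log2_ebgm"] = np.log2(df["ebgm"])
        df["log2_ebgm05"] = np.log2(df["ebgm05"])
    return df
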