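"""Independent oracles shared between unit and acceptance tests.

Everything here deliberately avoids the package's own code paths: Fisher
p-values by full hypergeometric enumeration, and MGPS posterior moments by
numerical integration of prior x likelihood (no conjugate shortcut).
"""

import math

import numpy as np
from scipy import integrate, stats
from scipy.stats import hypergeom


def enumerate_margin_pvalues(n, r1, n1):
    """Two-sided Fisher p for every feasible a at fixed margins (n, r1, n1):
    sum of the probabilities of all tables no more probable than observed."""
    lo, hi = max(0, n1 - (n - r1)), min(r1, n1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom(n, r1, n1).pmf(support)
    return support, np.array([pmf[pmf <= pmf[i] * (1 + 1e-9)].sum()
                              for i in range(len(support))])


def sweep_fisher_against_enumeration(fisher_volcano, table_cls, max_n):
    """Assert the implementation's Fisher p equals the enumeration oracle on
    every 2x2 table with N <= max_n; returns the number of tables checked."""
    checked = 0
    for n in range(2, max_n + 1):
        tables, expected = [], []
        for r1 in range(0, n + 1):
            for n1 in range(0, n + 1):
                support, oracle_ps = enumerate_margin_pvalues(n, r1, n1)
                for a, p_oracle in zip(support, oracle_ps):
                    b, c = int(r1 - a), int(n1 - a)
                    tables.append(table_cls(int(a), b, c, n - r1 - c))
                    expected.append(p_oracle)
        for t, (p, _, _), p_oracle in zip(tables, fisher_volcano(tables), expected):
            assert math.isclose(p, p_oracle, rel_tol=1e-9, abs_tol=1e-12), \
                (t.a, t.b, t.c, t.d, p, p_oracle)
        checked += len(tables)
    return checked


def ebgm_by_numerical_integration(a, e, prior):
    """Posterior geometric mean and 5th percentile of lambda by quadrature
    over prior(lambda) * Poisson(a | lambda * E)."""
    def prior_pdf(lam):
        return (prior.mix_p * stats.gamma.pdf(lam, prior.alpha1, scale=1 / prior.beta1)
                + (1 - prior.mix_p) * stats.gamma.pdf(lam, prior.alpha2, scale=1 / prior.beta2))

    def joint(lam):
        return prior_pdf(lam) * stats.poisson.pmf(a, lam * e)

    # integrate over a bracket that certainly contains the posterior mass,
    # with breakpoints at the likelihood peak so quad resolves narrow modes
    mode = max(a, 1) / e
    upper = mode + 20 * math.sqrt(max(a, 1)) / e + 50 / (1 + e)
    pts = sorted({mode * f for f in (0.25, 0.5, 1.0, 2.0)} | {0.01, 1.0})
    pts = [p for p in pts if 0 < p < upper]

    z, _ = integrate.quad(joint, 0, upper, limit=500, points=pts)
    mean_log, _ = integrate.quad(lambda l: np.log(l) * joint(l), 1e-300, upper,
                                 limit=500, points=pts)
    ebgm = math.exp(mean_log / z)

    def cdf(x):
        return integrate.quad(joint, 0, x, limit=500,
                              points=[p for p in pts if p < x])[0] / z

    lo, hi = 1e-12, upper
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if cdf(mid) < 0.05:
            lo = mid
        else:
            hi = mid
    return ebgm, 0.5 * (lo + hi)


def simulate_mgps_pairs(prior, n_pairs, rng):
    """Draw (a, E) pairs from the gamma-Poisson mixture model."""
    e = rng.lognormal(1.0, 1.0, n_pairs)
    comp = rng.random(n_pairs) < prior.mix_p
    lam = np.where(comp,
                   rng.gamma(prior.alpha1, 1 / prior.beta1, n_pairs),
                   rng.gamma(prior.alpha2, 1 / prior.beta2, n_pairs))
    a = rng.poisson(lam * e)
    return a, e
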