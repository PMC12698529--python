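import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

import oracles
from pvalopecia import disproportionality as dp
from pvalopecia.case_definition import DrugCaseIndex
from pvalopecia.disproportionality import (ContingencyTable, compute_ic,
                                           compute_prr, compute_ror,
                                           evaluate_signal, fisher_volcano)

WORKED = ContingencyTable(10, 90, 100, 9900)

cells = st.tuples(st.integers(0, 60), st.integers(0, 400),
                  st.integers(0, 400), st.integers(1, 20000))
pos_cells = st.tuples(st.integers(1, 60), st.integers(1, 400),
                      st.integers(1, 400), st.integers(1, 20000))


class TestContingency:
    def test_cells_from_index(self):
        drug = frozenset(f"d{i}" for i in range(100))
        event = frozenset(f"d{i}" for i in range(10)) | frozenset(f"e{i}" for i in range(100))
        universe = drug | event | frozenset(f"x{i}" for i in range(9900))
        idx = DrugCaseIndex(drug_cases={"X": drug}, event_cases=event, all_cases=universe)
        t = dp.build_contingency(idx, "X")
        assert (t.a, t.b, t.c, t.d) == (10, 90, 100, 9900)

    def test_zero_overlap(self):
        idx = DrugCaseIndex(drug_cases={"X": frozenset({"1"})},
                            event_cases=frozenset({"2"}),
                            all_cases=frozenset({"1", "2", "3"}))
        assert dp.build_contingency(idx, "X").a == 0

    def test_missing_drug_raises(self):
        idx = DrugCaseIndex(all_cases=frozenset({"1"}))
        with pytest.raises(KeyError):
            dp.build_contingency(idx, "X")

    def test_cells_match_brute_force_recount(self, fixture_cases, fixture_index):
        """Independent oracle: recount cells by set intersection over the raw
        case list for a handful of fixture drugs."""
        event = fixture_index.event_cases
        n = len(fixture_cases)
        for drug in ["DOCETAXEL", "MINOXIDIL", "DRUG_000"]:
            t = dp.build_contingency(fixture_index, drug)
            with_drug = {c.primaryid for c in fixture_cases if drug in c.drug_names()}
            a = sum(1 for c in fixture_cases
                    if c.primaryid in with_drug and c.primaryid in event)
            assert t.a == a
            assert t.b == len(with_drug) - a
            assert t.c == len(event) - a
            assert t.n == n


class TestClosedForms:
    def test_ror_worked_example(self):
        r = compute_ror(WORKED)
        assert r.ror == pytest.approx(11.0)
        assert r.lo == pytest.approx(5.56, abs=0.01)
        assert r.hi == pytest.approx(21.77, abs=0.01)

    def test_ror_symmetric_table_is_one(self):
        assert compute_ror(ContingencyTable(25, 25, 25, 25)).ror == pytest.approx(1.0)

    def test_ror_zero_cell_marker_and_haldane(self):
        t = ContingencyTable(0, 50, 50, 1000)
        assert math.isnan(compute_ror(t).ror)
        r = compute_ror(t, haldane=True)
        assert r.ror == pytest.approx((0.5 * 1000.5) / (50.5 * 50.5))

    def test_prr_worked_example(self):
        r = compute_prr(WORKED)
        assert r.prr == pytest.approx(10.0)
        assert r.chi2 == pytest.approx(74.447, abs=0.001)

    def test_prr_homogeneous_table(self):
        r = compute_prr(ContingencyTable(10, 90, 100, 900))
        assert r.prr == pytest.approx(1.0)
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_yates_strictly_smaller(self):
        assert compute_prr(WORKED, yates=True).chi2 < compute_prr(WORKED).chi2

    def test_ic_worked_example(self):
        r = compute_ic(WORKED)
        assert WORKED.expected == pytest.approx(1.0891, abs=1e-4)
        assert r.ic == pytest.approx(2.724, abs=0.001)
        assert r.ic025 == pytest.approx(1.647, abs=0.001)

    def test_ic_unshrunk_variant(self):
        assert compute_ic(WORKED, shrunk=False).ic == pytest.approx(3.199, abs=0.001)

    def test_ic_near_zero_when_observed_equals_expected(self):
        t = ContingencyTable(500, 4500, 500, 4500)  # E = 500 exactly
        assert abs(compute_ic(t).ic) < 0.01

    def test_ic_mc_mode_agrees_with_closed_form(self):
        """The seeded Monte-Carlo interval reproduces the closed-form point
        estimate exactly and the Noren bound closely for well-filled cells."""
        for t in (WORKED, ContingencyTable(50, 450, 300, 20000)):
            mc = dp.compute_ic_mc(t, seed=1)
            cf = compute_ic(t)
            assert mc.ic == cf.ic
            assert mc.ic025 == pytest.approx(cf.ic025, abs=0.1)
            assert mc.ic025 < mc.ic
        assert dp.compute_ic_mc(WORKED, seed=1) == dp.compute_ic_mc(WORKED, seed=1)

    @given(pos_cells)
    def test_closed_forms_match_independent_reevaluation(self, cells_):
        """Spelled-out formula re-evaluation as an independent oracle."""
        a, b, c, d = cells_
        t = ContingencyTable(a, b, c, d)
        n = a + b + c + d
        assert compute_ror(t).ror == pytest.approx((a / b) / (c / d), rel=1e-12)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert compute_ror(t).hi / compute_ror(t).ror == pytest.approx(
            math.exp(1.959963984540054 * se), rel=1e-12)
        assert compute_prr(t).prr == pytest.approx((a / (a + b)) / (c / (c + d)), rel=1e-12)
        exp = [[(a + b) * (a + c) / n, (a + b) * (b + d) / n],
               [(c + d) * (a + c) / n, (c + d) * (b + d) / n]]
        obs = [[a, b], [c, d]]
        chi2 = sum((obs[i][j] - exp[i][j]) ** 2 / exp[i][j]
                   for i in range(2) for j in range(2))
        assert compute_prr(t).chi2 == pytest.approx(chi2, rel=1e-9)
        e = (a + b) * (a + c) / n
        assert compute_ic(t).ic == pytest.approx(
            math.log((a + 0.5) / (e + 0.5)) / math.log(2), rel=1e-12)

    @given(cells)
    def test_sign_agreement_and_interval_order(self, cells_):
        """ROR > 1 iff PRR > 1 iff ad > bc; IC025 < IC always."""
        a, b, c, d = cells_
        t = ContingencyTable(a, b, c, d)
        ror, prr, ic = compute_ror(t), compute_prr(t), compute_ic(t)
        if not (math.isnan(ror.ror) or math.isnan(prr.prr)):
            assert (ror.ror > 1) == (prr.prr > 1) == (a * d > b * c)
            assert ror.lo < ror.ror < ror.hi
        assert ic.ic025 < ic.ic


class TestJointRule:
    PRIOR = dp.MgpsPrior(0.2, 0.1, 2.0, 4.0, 1 / 3)

    def _result(self, t):
        return evaluate_signal("X", t, compute_ror(t), compute_prr(t),
                               compute_ic(t), dp.compute_ebgm(t, self.PRIOR))

    def test_count_floor_blocks_positivity(self):
        t = ContingencyTable(2, 1, 5, 10000)  # huge effect, a < 3
        res = self._result(t)
        assert not res.positive
        assert not res.flags["ror_pos"] and not res.flags["prr_pos"]

    def test_worked_table_positive_end_to_end(self):
        res = self._result(WORKED)
        assert res.flags == {"ror_pos": True, "prr_pos": True,
                             "bcpnn_pos": True, "mgps_pos": True}
        assert res.positive

    def test_homogeneous_table_all_flags_false(self):
        res = self._result(ContingencyTable(10, 90, 100, 900))
        assert not any(res.flags.values())
        assert not res.positive

    def test_undefined_statistic_fails_flag(self):
        t = ContingencyTable(5, 0, 10, 1000)
        res = self._result(t)
        assert not res.flags["ror_pos"]


def exact_fisher_two_sided(a, b, c, d):
    """Independent oracle: full hypergeometric enumeration, summing the
    probability of every table (same margins) no more probable than the
    observed one."""
    r1, n1 = a + b, a + c
    n = a + b + c + d
    rv = hypergeom(n, r1, n1)
    p_obs = rv.pmf(a)
    lo, hi = max(0, n1 - (n - r1)), min(r1, n1)
    return float(sum(rv.pmf(k) for k in range(lo, hi + 1)
                     if rv.pmf(k) <= p_obs * (1 + 1e-9)))


class TestFisherVolcano:
    def test_small_table_exact_value(self):
        (p, p_adj, _), = fisher_volcano([ContingencyTable(3, 1, 1, 3)])
        assert p == pytest.approx(34 / 70, rel=1e-9)
        assert p_adj == p  # m = 1 identity

    def test_bonferroni_clipping(self):
        tables = [ContingencyTable(5, 5, 5, 5)] * 64
        for p, p_adj, _ in fisher_volcano(tables):
            assert p_adj == min(1.0, 64 * p)
        assert fisher_volcano(tables)[0][1] == 1.0

    def test_spelled_out_oracle_agrees_with_vectorised_oracle(self):
        for a, b, c, d in [(3, 1, 1, 3), (0, 5, 5, 0), (2, 8, 6, 4), (7, 0, 3, 10)]:
            support, ps = oracles.enumerate_margin_pvalues(a + b + c + d, a + b, a + c)
            assert ps[list(support).index(a)] == pytest.approx(
                exact_fisher_two_sided(a, b, c, d), rel=1e-12)

    def test_matches_enumeration_oracle_on_small_margin_sweep(self):
        """Exhaustive sweep of every small 2x2 (the full N <= 40 sweep runs
        in the acceptance suite)."""
        oracles.sweep_fisher_against_enumeration(fisher_volcano, ContingencyTable, 24)
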