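import math

import numpy as np
import pytest

from pvalopecia import datasets
from pvalopecia import stratification as st
from pvalopecia.faers_io import CaseReport, DrugEntry, parse_partial_date
from pvalopecia.stratification import (StratumSpec, age_band, baseline_summary,
                                       category_shares, classify_risk_tier,
                                       label_crosscheck, percentage,
                                       pt_level_distribution, risk_tier,
                                       round_half_up, stratified_signals)


def make_case(pid, sex="F", age=50.0, pts=("Alopecia",), drugs=(("X", "PS"),),
              outcomes=(), fda="20180315", country="US", occp="CN"):
    return CaseReport(
        primaryid=str(pid), caseid=str(pid), fda_dt=parse_partial_date(fda),
        age_years=age, sex=sex, reporter_occupation=occp, country=country,
        outcomes=frozenset(outcomes),
        drugs=[DrugEntry(drug_name=n, role=r) for n, r in drugs],
        reaction_pts=frozenset(pts),
    )


class TestRounding:
    @pytest.mark.parametrize("x, nd, want", [
        (76.815, 2, 76.82), (18.75, 1, 18.8), (23.4375, 1, 23.4),
        (2.5, 0, 3.0), (76.824999, 2, 76.82),
    ])
    def test_half_up(self, x, nd, want):
        assert round_half_up(x, nd) == want

    def test_reference_population_shares(self):
        """The bundled baseline counts reproduce the published percentages
        exactly (counts / 181,049 population, half-up to 2 decimals)."""
        base = datasets.load_baseline_counts()
        total = base.loc[base.block == "sex", "count"].sum()
        assert total == 181_049

        def share(block, level):
            n = int(base.loc[(base.block == block) & (base.level == level), "count"].iloc[0])
            return percentage(n, total)

        assert share("sex", "F") == 76.82
        assert share("severity", "serious") == 46.69
        assert share("occupation", "consumer") == 55.88
        assert share("region", "US") == 74.12
        assert share("reporting_year", "2016Q1-2020Q4") == 48.26


class TestBaselineSummary:
    def test_counts_and_percentages(self):
        cases = [make_case(i, sex="F" if i < 3 else "M", outcomes=({"HO"} if i == 0 else ()))
                 for i in range(4)]
        df = baseline_summary(cases)
        sex = df[df.block == "sex"].set_index("level")
        assert sex.loc["F", "count"] == 3 and sex.loc["F", "percent"] == 75.0
        sev = df[df.block == "severity"].set_index("level")
        assert sev.loc["serious", "count"] == 1

    def test_all_unknown_sex_is_100_percent(self):
        df = baseline_summary([make_case(i, sex="unknown") for i in range(5)])
        sex = df[df.block == "sex"].set_index("level")
        assert sex.loc["unknown", "percent"] == 100.00

    def test_exhaustive_blocks_sum_to_100(self, fixture_cases):
        df = baseline_summary(fixture_cases[:5000])
        for block in ("sex", "severity", "reporting_year", "region", "occupation"):
            s = df.loc[(df.block == block) & df.percent.notna(), "percent"].sum()
            if block == "reporting_year":  # years outside the bins are possible
                assert s <= 100.05
            else:
                assert s == pytest.approx(100.0, abs=0.05)

    def test_restricted_to_event_cases(self):
        cases = [make_case(1, pts=("Alopecia",)), make_case(2, pts=("Nausea",))]
        df = baseline_summary(cases, event_ids={"1"})
        assert df[df.block == "sex"]["count"].sum() == 1


class TestAgeBands:
    @pytest.mark.parametrize("age, band", [
        (0, "<18"), (17.9, "<18"), (18, "18-44"), (44.9, "18-44"),
        (45, "45-64"), (64.9, "45-64"), (65, ">=65"), (100, ">=65"),
        (None, None),
    ])
    def test_boundaries(self, age, band):
        assert age_band(age) == band


class TestStratifiedSignals:
    def _cases(self):
        """Planted sex-specific effect: drug Z causes the event in males
        only; drug B is a uniform background drug."""
        cases = []
        pid = 0
        for sex in ("M", "F"):
            for i in range(300):
                pid += 1
                drug = "Z" if i < 100 else "B"
                is_event = (drug == "Z" and sex == "M" and i < 40) or (i % 50 == 0)
                cases.append(make_case(pid, sex=sex,
                                       pts=("Alopecia",) if is_event else ("Nausea",),
                                       drugs=((drug, "PS"),)))
        return cases

    def test_effect_detected_only_in_planted_stratum(self):
        cases = self._cases()
        event_ids = {c.primaryid for c in cases if "Alopecia" in c.reaction_pts}
        out = stratified_signals(cases, event_ids,
                                 [StratumSpec(sex="M"), StratumSpec(sex="F")])
        male = out["sex M"].set_index("drug_name")
        female = out["sex F"].set_index("drug_name")
        assert bool(male.loc["Z", "positive"])
        assert not bool(female.loc["Z", "positive"])

    def test_whole_population_stratum_equals_unstratified(self):
        from pvalopecia.case_definition import build_drug_case_index
        from pvalopecia.disproportionality import signal_table
        cases = self._cases()
        event_ids = {c.primaryid for c in cases if "Alopecia" in c.reaction_pts}
        whole = stratified_signals(cases, event_ids, [StratumSpec()])["all"]
        direct = signal_table(build_drug_case_index(cases, event_ids))
        for col in ("a", "b", "c", "d", "ror", "prr", "ic", "fisher_p", "positive"):
            assert list(whole[col]) == list(direct[col])

    def test_bonferroni_family_is_stratum_drug_count(self):
        cases = self._cases()
        event_ids = {c.primaryid for c in cases if "Alopecia" in c.reaction_pts}
        df = stratified_signals(cases, event_ids, [StratumSpec(sex="M")])["sex M"]
        m = len(df)
        for _, row in df.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, m * row["fisher_p"]))

    def test_category_stratum_restricts_drug_family(self):
        cases = self._cases()
        event_ids = {c.primaryid for c in cases if "Alopecia" in c.reaction_pts}
        cats = {"Z": "oncology", "B": "other"}
        # narrow strata cannot fit their own empirical-Bayes prior; share
        # the whole-database one
        from pvalopecia.case_definition import build_drug_case_index
        from pvalopecia.disproportionality import build_contingency, fit_mgps_prior
        idx = build_drug_case_index(cases, event_ids)
        prior = fit_mgps_prior([build_contingency(idx, d) for d in idx.drugs()])
        out = stratified_signals(cases, event_ids,
                                 [StratumSpec(category="oncology")],
                                 drug_categories=cats, prior=prior)
        df = out["category oncology"]
        assert list(df.drug_name) == ["Z"]
        # Bonferroni family is the single drug in the category
        assert df.iloc[0].p_adjusted == pytest.approx(min(1.0, df.iloc[0].fisher_p))

    def test_category_stratum_without_map_is_an_error(self):
        cases = self._cases()
        with pytest.raises(ValueError, match="drug_categories"):
            stratified_signals(cases, {"1"}, [StratumSpec(category="oncology")])

    def test_stratum_a_cells_sum_to_at_most_unstratified(self, ):
        cases = self._cases() + [make_case(9999, sex="unknown", drugs=(("Z", "PS"),))]
        event_ids = {c.primaryid for c in cases if "Alopecia" in c.reaction_pts}
        out = stratified_signals(cases, event_ids,
                                 [StratumSpec(sex="M"), StratumSpec(sex="F")])
        from pvalopecia.case_definition import build_drug_case_index
        from pvalopecia.disproportionality import build_contingency
        idx = build_drug_case_index(cases, event_ids)
        for drug in ("Z", "B"):
            total = build_contingency(idx, drug).a
            parts = sum(int(df.set_index("drug_name").loc[drug, "a"])
                        for df in out.values())
            assert parts <= total


class TestRiskTiers:
    @pytest.mark.parametrize("ic025, tier", [
        (5.61, "high"), (2.87, "medium"), (1.5, "low"), (3.0, "medium"),
        (3.0001, "high"), (0.0, "low"), (-2.0, "low"),
    ])
    def test_boundaries(self, ic025, tier):
        assert risk_tier(ic025) == tier

    def test_reference_signal_drugs_tier_6_26_32(self):
        ref = datasets.load_signal_reference()
        tiers, counts = classify_risk_tier(dict(zip(ref.drug_name, ref.ic025)))
        assert counts == {"high": 6, "medium": 26, "low": 32}
        assert sum(counts.values()) == len(tiers) == 64

    def test_missing_ic025_left_unclassified(self):
        tiers, counts = classify_risk_tier({"A": 2.0, "B": math.nan})
        assert "B" not in tiers and sum(counts.values()) == 1


class TestPtLevelDistribution:
    CASES = [
        make_case(1, pts=("PT-x",), drugs=(("A", "PS"),)),
        make_case(2, pts=("PT-x",), drugs=(("A", "PS"),)),
        make_case(3, pts=("PT-x",), drugs=(("A", "PS"), ("B", "PS"))),
        make_case(4, pts=("PT-x",), drugs=(("B", "PS"),)),
        make_case(5, pts=("PT-y",), drugs=(("C", "PS"),)),
    ]

    def test_hand_counted_shares(self):
        df = pt_level_distribution(self.CASES, ["PT-x", "PT-y"])
        x = df[df.pt == "PT-x"].set_index("drug_name")
        assert x.loc["A", "share_pct"] == 75.0  # 3 of 4
        assert x.loc["B", "share_pct"] == 50.0

    def test_single_drug_pt_is_100(self):
        df = pt_level_distribution(self.CASES, ["PT-y"])
        assert df.iloc[0].drug_name == "C" and df.iloc[0].share_pct == 100.0

    def test_each_drug_share_at_most_100(self):
        df = pt_level_distribution(self.CASES, ["PT-x", "PT-y"])
        assert (df.share_pct <= 100.0).all()


class TestLabelCrosscheck:
    def test_reference_49_15_split(self):
        ref = datasets.load_signal_reference()
        ann = datasets.load_synthetic_label_annotations()
        out = label_crosscheck(ref.drug_name.tolist(), ann)
        assert len(out["documented"]) == 49 and len(out["undocumented"]) == 15
        assert out["documented_pct"] == 76.6
        assert out["undocumented_pct"] == 23.4

    def test_none_documented(self):
        ann = [st.LabelAnnotation("A", False), st.LabelAnnotation("B", False)]
        out = label_crosscheck(["A", "B"], ann)
        assert out["documented_pct"] == 0.0

    def test_missing_annotation_counted_unknown(self):
        out = label_crosscheck(["A", "B"], [st.LabelAnnotation("A", True)])
        assert out["unknown"] == ["B"] and out["n_total"] == 2


def test_category_shares_reference():
    ref = datasets.load_signal_reference()
    shares = category_shares(ref.category.value_counts().to_dict(), total=64)
    assert shares["oncology"] == 37.5
    assert shares["endocrine"] == 18.8
    assert shares["immune"] == 10.9
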