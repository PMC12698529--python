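#!/usr/bin/env python
"""Subgroup signals, risk tiers and reference bookkeeping.

Re-runs the screen within sex and age strata (stratum-restricted 2x2,
Bonferroni family = drugs per stratum) on the simulated study, then applies
the IC025 tier rule both to the simulated positives and to the bundled
64-drug reference signal table, and computes the reference category shares
and label-documentation gap.  Writes results/stratified_signals.csv,
results/risk_tiers.csv and results/reference_bookkeeping.json.
"""

import json
from pathlib import Path

import pandas as pd

from pvalopecia import case_definition as cd
from pvalopecia import datasets
from pvalopecia import stratification as strat
from pvalopecia.pipeline import DEFAULT_STRATA

import importlib.util as _iu
_spec = _iu.spec_from_file_location("describe", Path(__file__).parent / "02_describe.py")
_describe = _iu.module_from_spec(_spec)
_spec.loader.exec_module(_describe)

ROOT = Path(__file__).resolve().parent.parent


def main():
    cases = _describe.load_cases()
    event_ids = cd.flag_event_cases(cases, datasets.load_alopecia_smq())

    per_stratum = strat.stratified_signals(cases, event_ids, DEFAULT_STRATA)
    frames = [df for df in per_stratum.values() if not df.empty]
    stratified = pd.concat(frames, ignore_index=True)
    stratified.to_csv(ROOT / "results" / "stratified_signals.csv", index=False)
    for name, df in per_stratum.items():
        if df.empty:
            continue
        lost = df[df.lost_significance]
        print(f"stratum {name}: {int(df.positive.sum())} positive drugs, "
              f"{len(lost)} lost significance after Bonferroni")

    signals = pd.read_csv(ROOT / "results" / "signals.csv")
    tiers, counts = strat.classify_risk_tier(
        dict(zip(signals[signals.positive].drug_name,
                 signals[signals.positive].ic025)))
    pd.DataFrame(sorted(tiers.items()), columns=["drug_name", "tier"]) \
        .to_csv(ROOT / "results" / "risk_tiers.csv", index=False)
    print(f"simulated positives by tier: {counts}")

    ref = datasets.load_signal_reference()
    _, ref_counts = strat.classify_risk_tier(dict(zip(ref.drug_name, ref.ic025)))
    shares = strat.category_shares(ref.category.value_counts().to_dict(), total=len(ref))
    check = strat.label_crosscheck(ref.drug_name.tolist(),
                                   datasets.load_synthetic_label_annotations())
    book = {"reference_tier_counts": ref_counts,
            "reference_category_shares_pct": shares,
            "reference_label_documented_pct": check["documented_pct"],
            "reference_label_undocumented_pct": check["undocumented_pct"]}
    (ROOT / "results" / "reference_bookkeeping.json").write_text(
        json.dumps(book, indent=2))
    print(f"reference signal table: tiers {ref_counts}, "
          f"label gap {check['undocumented_pct']}% undocumented")


if __name__ == "__main__":
    main()
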