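#!/usr/bin/env python
"""Descriptive baseline of the event cases in the simulated study.

Reads results/synthetic/, de-duplicates, flags alopecia cases against the
packaged narrow SMQ term list, and writes the Table-1-style summary to
results/baseline.csv.  Also prints the reference population shares from the
bundled baseline counts for comparison with the synthetic population.
"""

from pathlib import Path

from pvalopecia import case_definition as cd
from pvalopecia import datasets, faers_io
from pvalopecia import stratification as strat

ROOT = Path(__file__).resolve().parent.parent
TABLES = ROOT / "results" / "synthetic"


def load_cases():
    read = lambda n: faers_io.read_faers_table(TABLES / f"{n}.txt", n)
    demo = faers_io.deduplicate(read("DEMO"))
    return faers_io.assemble_cases(demo, read("DRUG"), read("REAC"),
                                   read("THER"), read("OUTC"))


def main():
    cases = load_cases()
    event_ids = cd.flag_event_cases(cases, datasets.load_alopecia_smq())
    df = strat.baseline_summary(cases, event_ids)
    out = ROOT / "results" / "baseline.csv"
    df.to_csv(out, index=False)

    sex = df[df.block == "sex"].set_index("level")
    sev = df[df.block == "severity"].set_index("level")
    print(f"{len(event_ids)} alopecia cases among {len(cases)} assembled cases")
    print(f"female share {sex.loc['F', 'percent']}% "
          f"(reference population: 76.82%)")
    print(f"serious share {sev.loc['serious', 'percent']}% "
          f"(reference population: 46.69%)")
    print(f"baseline summary -> {out}")


if __name__ == "__main__":
    main()
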