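#!/usr/bin/env python
"""Generate the study database: the packaged reference-scale fixture.

Writes the five FAERS-style tables plus the planted ground truth under
results/synthetic/.  The fixture plants 71 strong alopecia-signal drugs
(relative reporting rates 55-75) among 400 drugs over 40,000 cases; 7 of the
71 are drugs indicated for alopecia itself, which the later exclusion step
must remove.
"""

import json
from pathlib import Path

from pvalopecia import synthetic_data as sd

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main():
    bundle = sd.make_reference_scale_fixture()
    paths = sd.write_tables(bundle.tables, OUT)
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump({"rr": bundle.truth.rr,
                   "tto_params": bundle.truth.tto_params,
                   "duplicate_map": bundle.truth.duplicate_map,
                   "exclusion_list": list(bundle.exclusion_list)}, fh, indent=2)
    n_dup = len(bundle.truth.duplicate_map)
    print(f"wrote {len(paths)} tables to {OUT}")
    print(f"{bundle.config.n_cases} cases, {len(bundle.config.drugs)} drugs, "
          f"{len(bundle.signal_drugs)} planted signal drugs, "
          f"{n_dup} duplicated case versions")


if __name__ == "__main__":
    main()
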