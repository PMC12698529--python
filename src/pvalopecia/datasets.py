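"""Packaged reference data.

Small CSVs shipped with the package:

* ``alopecia_smq_narrow.csv`` — a seed narrow-scope alopecia PT list built
  from publicly named preferred terms.  MedDRA is licensed and its official
  SMQ cannot be redistributed; users must substitute the licensed term list
  for real analyses.
* ``signal_reference.csv`` — a curated reference table of 64 alopecia-signal
  drugs from a large published FAERS disproportionality screen (drug,
  therapeutic category, report count, ROR with CI, PRR with chi-square, IC
  with IC025).  Used for category-share, risk-tier and label bookkeeping and
  as a realistic drug roster for the packaged fixture.
* ``label_annotations_synthetic.csv`` — drug -> alopecia-documented flag for
  the 64 reference drugs.  SYNTHETIC: the four undocumented drugs that are
  publicly named are annotated as such; the remaining undocumented rows are
  an illustrative assignment reproducing the reference 49/15 split.
* ``tto_reference.csv`` — reference per-drug time-to-onset summaries
  (n, median, Q1, Q3 in days) for the signal drugs with usable date pairs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .case_definition import SmqTermList, load_smq_csv
from .stratification import LabelAnnotation, load_label_annotations


def _data_path(name: str) -> Path:
    return Path(resources.files("pvalopecia").joinpath("data", name))


def load_alopecia_smq() -> SmqTermList:
    """Seed narrow-scope alopecia SMQ term list (editable packaged CSV)."""
    return load_smq_csv(_data_path("alopecia_smq_narrow.csv"),
                        name="alopecia (seed narrow SMQ)", scope="narrow")


def load_signal_reference() -> pd.DataFrame:
    """Reference signal table: 64 drugs with category, report count and the
    four disproportionality statistics."""
    return pd.read_csv(_data_path("signal_reference.csv"))


def load_baseline_counts() -> pd.DataFrame:
    """Reference baseline (Table-1-style) count blocks for the alopecia
    report population: block, level, count."""
    return pd.read_csv(_data_path("baseline_counts.csv"))


def load_synthetic_label_annotations() -> list:
    return load_label_annotations(_data_path("label_annotations_synthetic.csv"))


def load_tto_reference() -> pd.DataFrame:
    return pd.read_csv(_data_path("tto_reference.csv"))
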