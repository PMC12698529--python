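"""Synthetic FAERS-like spontaneous-report generator with known ground truth.

The generator emits the same five ``$``-delimited tables the readers consume
(DEMO, DRUG, REAC, THER, OUTC), with the multi-table case structure keyed by
PRIMARYID/CASEID, duplicate case versions, drug role codes, per-case PT
lists, demographics skewed female with an adult age distribution,
per-drug relative reporting-rate multipliers for the target event, and
per-drug Weibull-distributed onset latencies with partial/missing dates.

Default demographic parameters mirror a large drug-induced alopecia report
population: 76.82% female reports, 13% unknown sex, adult ages 53.84 +/- 16.28
years with 41.42% missing, 71.53% missing weight, 46.69% serious, and a
target-event background reporting probability of 0.008.  Everything is
deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .faers_io import RawRecordSet

TARGET_PTS = (
    "Alopecia", "Alopecia areata", "Alopecia totalis", "Alopecia universalis",
    "Androgenetic alopecia", "Diffuse alopecia", "Hypotrichosis",
)

OUTCOME_CODE_P = {"OT": 0.60, "HO": 0.155, "DS": 0.082, "LT": 0.032,
                  "DE": 0.030, "RI": 0.006, "CA": 0.006, "": 0.089}

DEMO_COLUMNS = ("primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
                "sex", "wt", "wt_cod", "occp_cod", "occr_country")
DRUG_COLUMNS = ("primaryid", "caseid", "drug_seq", "role_cod", "drugname", "route")
REAC_COLUMNS = ("primaryid", "caseid", "pt")
THER_COLUMNS = ("primaryid", "caseid", "dsg_drug_seq", "start_dt")
OUTC_COLUMNS = ("primaryid", "caseid", "outc_cod")

_EPOCH = date(1970, 1, 1).toordinal()


class SyntheticConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic database.

    ``effect_map`` plants per-drug relative reporting rates for the target
    event (RR=1 where absent); ``tto_params`` plants per-drug Weibull
    (shape, scale-days) latencies, falling back to ``default_tto``.
    """

    n_cases: int = 20_000
    n_drugs: int = 100
    n_background_pts: int = 60
    effect_map: Mapping[str, float] = field(default_factory=dict)
    event_base_rate: float = 0.008
    female_share: float = 0.7682
    unknown_sex_rate: float = 0.13
    age_mean: float = 53.84
    age_sd: float = 16.28
    missing_age_rate: float = 0.4142
    missing_weight_rate: float = 0.7153
    serious_rate: float = 0.4669
    tto_params: Mapping[str, tuple] = field(default_factory=dict)
    default_tto: tuple = (1.2, 120.0)
    duplicate_rate: float = 0.05
    missing_date_rate: float = 0.30
    partial_date_rate: float = 0.10
    concomitant_rate: float = 0.0
    drug_names: Sequence[str] | None = None
    drug_weights: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self):
        bad = []
        for name in ("event_base_rate", "female_share", "unknown_sex_rate",
                     "missing_age_rate", "missing_weight_rate", "serious_rate",
                     "duplicate_rate", "missing_date_rate", "partial_date_rate",
                     "concomitant_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                bad.append(name)
        if self.female_share + self.unknown_sex_rate > 1:
            bad.append("female_share+unknown_sex_rate")
        if self.n_cases < 1:
            bad.append("n_cases")
        if self.n_drugs < 1 and self.drug_names is None:
            bad.append("n_drugs")
        if any(rr < 0 for rr in self.effect_map.values()):
            bad.append("effect_map")
        if bad:
            raise SyntheticConfigError(f"invalid config fields: {', '.join(bad)}")

    @property
    def drugs(self) -> list:
        if self.drug_names is not None:
            return list(self.drug_names)
        return [f"DRUG_{i:03d}" for i in range(self.n_drugs)]


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    rr: dict                 # drug -> relative reporting rate
    tto_params: dict         # drug -> (weibull shape, scale days)
    duplicate_map: dict      # caseid -> retained primaryid
    event_base_rate: float
    drug_probs: dict         # drug -> sampling probability per case

    def event_prob(self, drug: str) -> float:
        return min(1.0, self.event_base_rate * self.rr[drug])

    def implied_odds_ratio(self, drug: str) -> float:
        """The odds ratio the 2x2 estimates: target-event odds under the drug
        versus the mixture odds over all other drugs.  This, not the raw RR,
        is the estimand of the reporting odds ratio."""
        p1 = self.event_prob(drug)
        w_other = {d: w for d, w in self.drug_probs.items() if d != drug}
        z = sum(w_other.values())
        p0 = sum(w * self.event_prob(d) for d, w in w_other.items()) / z
        return (p1 / (1 - p1)) / (p0 / (1 - p0))


def _date_strings(ordinals: np.ndarray) -> np.ndarray:
    days = (ordinals - _EPOCH).astype("timedelta64[D]")
    iso = np.datetime_as_string(np.datetime64("1970-01-01") + days, unit="D")
    return np.char.replace(iso, "-", "")


def generate(config: SyntheticConfig) -> tuple[dict, GroundTruth]:
    """Draw one synthetic database.

    Each case draws one Primary-Suspect drug, reports the target event with
    probability min(1, base_rate * RR(drug)), carries 1+ background PTs, and
    gets a latency from the drug's Weibull encoded as start/event dates.  A
    ``duplicate_rate`` fraction of cases emit an extra, older DEMO version
    (with its own DRUG/REAC rows) that de-duplication must discard.

    Returns ``(tables, truth)`` where ``tables`` maps table name to
    :class:`~pvalopecia.faers_io.RawRecordSet`; identical configs produce
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drugs = config.drugs
    k = len(drugs)

    weights = (np.full(k, 1.0 / k) if config.drug_weights is None
               else np.asarray(config.drug_weights, dtype=float) / np.sum(config.drug_weights))
    rr = np.array([config.effect_map.get(d, 1.0) for d in drugs], dtype=float)
    p_event = np.clip(config.event_base_rate * rr, 0.0, 1.0)
    shapes = np.array([config.tto_params.get(d, config.default_tto)[0] for d in drugs])
    scales = np.array([config.tto_params.get(d, config.default_tto)[1] for d in drugs])

    caseid = np.arange(3_000_000, 3_000_000 + n)
    dup_mask = rng.random(n) < config.duplicate_rate
    version = np.where(dup_mask, 2, 1)
    primaryid = caseid * 10 + version

    drug_idx = rng.choice(k, size=n, p=weights)
    is_event = rng.random(n) < p_event[drug_idx]

    # demographics
    u = rng.random(n)
    sex = np.where(u < config.female_share, "F",
                   np.where(u < config.female_share + (1 - config.female_share - config.unknown_sex_rate),
                            "M", None))
    age = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, n)), 0, 100)
    age_missing = rng.random(n) < config.missing_age_rate
    age_cod = np.where(rng.random(n) < 0.02, "MON", "YR")
    age_val = np.where(age_cod == "MON", age * 12, age).astype(int)
    weight_kg = np.clip(rng.normal(75, 16, n), 35, 200)
    wt_missing = rng.random(n) < config.missing_weight_rate
    wt_cod = np.where(rng.random(n) < 0.3, "LBS", "KG")
    wt_val = np.round(np.where(wt_cod == "LBS", weight_kg / 0.4536, weight_kg), 1)
    occp = rng.choice(["CN", "MD", "PH", "LW", "OT"], size=n,
                      p=[0.57, 0.14, 0.12, 0.09, 0.08])
    country = rng.choice(["US", "CA", "GB", "FR", "DE", "JP"], size=n,
                         p=[0.7412, 0.0731, 0.0297, 0.0284, 0.0175, 0.1101])

    # dates: therapy start, Weibull latency, event and FDA receipt
    start_ord = rng.integers(date(2004, 1, 1).toordinal(),
                             date(2023, 7, 1).toordinal(), size=n)
    latency = np.round(scales[drug_idx] *
                       (-np.log1p(-rng.random(n))) ** (1.0 / shapes[drug_idx])).astype(int)
    event_ord = start_ord + latency
    fda_ord = np.minimum(event_ord + rng.integers(7, 120, size=n),
                         date(2024, 12, 31).toordinal())
    fda_ord = np.maximum(fda_ord, event_ord + 1)

    start_str = _date_strings(start_ord).astype(object)
    event_str = _date_strings(event_ord).astype(object)
    fda_str = _date_strings(fda_ord).astype(object)

    u_start = rng.random(n)
    start_str[u_start < config.missing_date_rate] = None
    partial = (u_start >= config.missing_date_rate) & \
              (u_start < config.missing_date_rate + config.partial_date_rate)
    for i in np.nonzero(partial)[0]:
        start_str[i] = start_str[i][:6]  # month precision
    u_event = rng.random(n)
    event_str[u_event < config.missing_date_rate] = None

    # outcomes / seriousness
    serious = rng.random(n) < config.serious_rate
    codes = [c for c in OUTCOME_CODE_P if c]
    code_p = np.array([OUTCOME_CODE_P[c] for c in codes])
    outc_code = rng.choice(codes, size=n, p=code_p / code_p.sum())

    # reaction PTs: one target PT for event cases + 1-3 background PTs for all
    bg_pool = np.array([f"Background PT {i:03d}" for i in range(config.n_background_pts)])
    n_bg = 1 + rng.poisson(0.8, size=n)
    target_pt = rng.choice(np.array(TARGET_PTS), size=n,
                           p=[0.62, 0.14, 0.06, 0.04, 0.05, 0.05, 0.04])

    drug_name_arr = np.array(drugs, dtype=object)[drug_idx]

    pid_s = primaryid.astype(str).astype(object)
    cid_s = caseid.astype(str).astype(object)

    def rows_from(columns, arrays):
        cols = [np.asarray(a, dtype=object) for a in arrays]
        return [dict(zip(columns, vals)) for vals in zip(*cols)]

    demo_rows = rows_from(DEMO_COLUMNS, [
        pid_s, cid_s, fda_str, event_str,
        np.where(age_missing, None, age_val.astype(str).astype(object)),
        np.where(age_missing, None, age_cod.astype(object)),
        sex,
        np.where(wt_missing, None, wt_val.astype(str).astype(object)),
        np.where(wt_missing, None, wt_cod.astype(object)),
        occp, country,
    ])

    drug_rows = rows_from(DRUG_COLUMNS, [
        pid_s, cid_s, np.full(n, "1", dtype=object), np.full(n, "PS", dtype=object),
        drug_name_arr, np.full(n, "ORAL", dtype=object),
    ])
    ther_rows = rows_from(THER_COLUMNS, [
        pid_s, cid_s, np.full(n, "1", dtype=object), start_str,
    ])

    # concomitant (non-suspect) drugs that must stay out of PS-only indexes
    if config.concomitant_rate > 0:
        con_mask = rng.random(n) < config.concomitant_rate
        idx = np.nonzero(con_mask)[0]
        other = (drug_idx[idx] + 1 + rng.integers(0, k - 1, size=len(idx))) % k
        drug_rows += rows_from(DRUG_COLUMNS, [
            pid_s[idx], cid_s[idx], np.full(len(idx), "2", dtype=object),
            np.full(len(idx), "C", dtype=object),
            np.array(drugs, dtype=object)[other], np.full(len(idx), "ORAL", dtype=object),
        ])

    # REAC: background PTs (possibly repeated draws) + the target PT
    rep_pid = np.repeat(pid_s, n_bg)
    rep_cid = np.repeat(cid_s, n_bg)
    bg_pts = bg_pool[rng.integers(0, config.n_background_pts, size=int(n_bg.sum()))]
    reac_rows = rows_from(REAC_COLUMNS, [rep_pid, rep_cid, bg_pts.astype(object)])
    ev = np.nonzero(is_event)[0]
    reac_rows += rows_from(REAC_COLUMNS, [pid_s[ev], cid_s[ev], target_pt[ev].astype(object)])

    outc_rows = rows_from(OUTC_COLUMNS, [pid_s[serious], cid_s[serious],
                                         outc_code[serious].astype(object)])

    # duplicate (stale) versions: older fda_dt, lower version number, own rows
    dup = np.nonzero(dup_mask)[0]
    duplicate_map = {}
    if len(dup):
        old_pid = (caseid[dup] * 10 + 1).astype(str).astype(object)
        old_fda = _date_strings(np.maximum(fda_ord[dup] - rng.integers(30, 400, size=len(dup)),
                                           date(2004, 1, 2).toordinal())).astype(object)
        demo_rows += rows_from(DEMO_COLUMNS, [
            old_pid, cid_s[dup], old_fda, event_str[dup],
            np.where(age_missing[dup], None, age_val[dup].astype(str).astype(object)),
            np.where(age_missing[dup], None, age_cod[dup].astype(object)),
            sex[dup],
            np.where(wt_missing[dup], None, wt_val[dup].astype(str).astype(object)),
            np.where(wt_missing[dup], None, wt_cod[dup].astype(object)),
            occp[dup], country[dup],
        ])
        drug_rows += rows_from(DRUG_COLUMNS, [
            old_pid, cid_s[dup], np.full(len(dup), "1", dtype=object),
            np.full(len(dup), "PS", dtype=object), drug_name_arr[dup],
            np.full(len(dup), "ORAL", dtype=object),
        ])
        reac_rows += rows_from(REAC_COLUMNS, [old_pid, cid_s[dup],
                                              np.full(len(dup), "Background PT 000", dtype=object)])
        duplicate_map = {str(c): str(p) for c, p in zip(caseid[dup], primaryid[dup])}

    tables = {
        "DEMO": RawRecordSet("DEMO", demo_rows),
        "DRUG": RawRecordSet("DRUG", drug_rows),
        "REAC": RawRecordSet("REAC", reac_rows),
        "THER": RawRecordSet("THER", ther_rows),
        "OUTC": RawRecordSet("OUTC", outc_rows),
    }
    truth = GroundTruth(
        rr={d: float(r) for d, r in zip(drugs, rr)},
        tto_params={d: (float(s), float(sc)) for d, s, sc in zip(drugs, shapes, scales)},
        duplicate_map=duplicate_map,
        event_base_rate=config.event_base_rate,
        drug_probs={d: float(w) for d, w in zip(drugs, weights)},
    )
    return tables, truth


_TABLE_COLUMNS = {"DEMO": DEMO_COLUMNS, "DRUG": DRUG_COLUMNS, "REAC": REAC_COLUMNS,
                  "THER": THER_COLUMNS, "OUTC": OUTC_COLUMNS}


def write_tables(tables: Mapping[str, RawRecordSet], outdir: str | Path) -> dict:
    """Write each table as a ``$``-delimited ASCII file; returns name->path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, rs in tables.items():
        columns = _TABLE_COLUMNS[name.upper()]
        path = outdir / f"{name.upper()}.txt"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("$".join(columns) + "\n")
            for row in rs.rows:
                fh.write("$".join("" if row.get(c) is None else str(row.get(c))
                                  for c in columns) + "\n")
        paths[name.upper()] = path
    return paths


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> dict:
    """Persist the planted parameters as a CSV pair: per-drug truth
    (RR, Weibull shape/scale, sampling probability) and the duplicate map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drugs_path = outdir / "ground_truth_drugs.csv"
    with open(drugs_path, "w", encoding="utf-8") as fh:
        fh.write("drug_name,rr,weibull_shape,weibull_scale,drug_prob\n")
        for d in truth.rr:
            shape, scale = truth.tto_params[d]
            fh.write(f"{d},{truth.rr[d]:g},{shape:g},{scale:g},"
                     f"{truth.drug_probs[d]:.10g}\n")
    dup_path = outdir / "ground_truth_duplicates.csv"
    with open(dup_path, "w", encoding="utf-8") as fh:
        fh.write("caseid,retained_primaryid\n")
        for caseid, pid in truth.duplicate_map.items():
            fh.write(f"{caseid},{pid}\n")
    return {"drugs": drugs_path, "duplicates": dup_path}


# ---------------------------------------------------------------------------
# packaged end-to-end fixture
# ---------------------------------------------------------------------------

#: drugs indicated for the target condition; reports against them reflect
#: treatment failure, so the pipeline excludes them post-signal
FIXTURE_EXCLUSION_LIST = (
    "MINOXIDIL", "FINASTERIDE", "DUTASTERIDE", "SPIRONOLACTONE",
    "BARICITINIB", "RITLECITINIB", "DEURUXOLITINIB",
)

FIXTURE_SEED = 20240401


@dataclass
class FixtureBundle:
    config: SyntheticConfig
    tables: dict
    truth: GroundTruth
    signal_drugs: tuple
    exclusion_list: tuple


def make_reference_scale_fixture() -> FixtureBundle:
    """A deterministic end-to-end fixture: 400 drugs over 40,000 cases with
    71 drugs planted at strong relative reporting rates (RR 55-75), of which
    7 are condition-indicated drugs on the exclusion list, so the signal
    funnel runs 71 positives -> 64 after exclusion.
    """
    from .datasets import load_signal_reference  # local import to avoid cycle

    ref = load_signal_reference()
    named = [d.upper() for d in ref["drug_name"].tolist()]  # 64 reference drugs
    signal_drugs = tuple(named + list(FIXTURE_EXCLUSION_LIST))  # 71 planted
    nulls = [f"DRUG_{i:03d}" for i in range(400 - len(signal_drugs))]
    rr_values = np.linspace(75.0, 55.0, len(signal_drugs))
    rng = np.random.default_rng(FIXTURE_SEED)
    tto = {d: (float(rng.choice([0.8, 1.0, 1.5])), float(rng.uniform(40, 260)))
           for d in signal_drugs}
    config = SyntheticConfig(
        n_cases=40_000,
        drug_names=list(signal_drugs) + nulls,
        effect_map={d: float(r) for d, r in zip(signal_drugs, rr_values)},
        tto_params=tto,
        duplicate_rate=0.05,
        seed=FIXTURE_SEED,
    )
    tables, truth = generate(config)
    return FixtureBundle(config=config, tables=tables, truth=truth,
                         signal_drugs=signal_drugs,
                         exclusion_list=FIXTURE_EXCLUSION_LIST)
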