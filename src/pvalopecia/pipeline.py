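"""End-to-end orchestration behind a validated YAML configuration.

``run_full`` executes ingest -> de-dup -> case definition -> signal
detection -> stratification -> risk tiers -> time-to-onset -> label
cross-check, writes every stage's tidy CSV under the output directory and
records a manifest: input checksums, a config echo, and the row-count funnel
from raw DEMO rows down to the final positive-drug count.  A stage failure
is recorded in the manifest with the partial outputs kept on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import case_definition, datasets, disproportionality, faers_io
from . import stratification as strat
from . import tto_analysis as tto

logger = logging.getLogger(__name__)


class ValidationFailure(ValueError):
    pass


class RunConfig(BaseModel):
    """Everything a full run needs; every screen-defining constant the
    pipeline uses is surfaced here with its conventional default."""

    demo: str
    drug: str
    reac: str
    ther: str | None = None
    outc: str | None = None
    smq_csv: str | None = None          # packaged seed list when omitted
    exclusion_csv: str | None = None
    label_csv: str | None = None
    synonym_csv: str | None = None
    out_dir: str = "results/run"
    role_filter: list[str] = Field(default_factory=lambda: ["PS"])
    min_a: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0
    yates: bool = False
    haldane: bool = False
    stratify: bool = True
    min_cases: int = 1
    tto_bin_edges: list[float] = Field(default_factory=lambda: list(tto.DEFAULT_BIN_EDGES))
    seed: int = 0

    @field_validator("role_filter")
    @classmethod
    def _roles_valid(cls, v):
        bad = set(v) - {"PS", "SS", "C", "I"}
        if bad:
            raise ValueError(f"invalid role codes: {bad}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def validate_paths(self) -> None:
        for name in ("demo", "drug", "reac", "ther", "outc",
                     "smq_csv", "exclusion_csv", "label_csv", "synonym_csv"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ValidationFailure(f"{name}: file not found: {value}")

    def thresholds(self) -> disproportionality.SignalThresholds:
        return disproportionality.SignalThresholds(
            min_a=self.min_a, prr_min=self.prr_min, chi2_min=self.chi2_min,
            ic025_gt=self.ic025_gt, ebgm05_gt=self.ebgm05_gt)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


DEFAULT_STRATA = tuple(
    [strat.StratumSpec(sex=s) for s in ("F", "M")]
    + [strat.StratumSpec(age_band=b) for b in strat.AGE_BANDS]
)


def run_full(config: RunConfig) -> dict:
    """Execute the whole pipeline; returns the manifest (also written as
    ``manifest.json`` in the output directory)."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "inputs": {}, "funnel": {}, "outputs": {}, "failed_stage": None,
    }
    for name in ("demo", "drug", "reac", "ther", "outc"):
        value = getattr(config, name)
        if value:
            manifest["inputs"][name] = {"path": str(value), "sha256": _checksum(value)}

    stage = "ingest"
    try:
        tables = {
            "DEMO": faers_io.read_faers_table(config.demo, "DEMO"),
            "DRUG": faers_io.read_faers_table(config.drug, "DRUG"),
            "REAC": faers_io.read_faers_table(config.reac, "REAC"),
            "THER": faers_io.read_faers_table(config.ther, "THER") if config.ther else None,
            "OUTC": faers_io.read_faers_table(config.outc, "OUTC") if config.outc else None,
        }
        manifest["funnel"]["raw_demo_rows"] = len(tables["DEMO"].rows)

        stage = "deduplicate"
        demo = faers_io.deduplicate(tables["DEMO"])
        manifest["funnel"]["deduplicated_cases"] = len(demo.rows)

        stage = "assemble"
        synonyms = None
        if config.synonym_csv:
            syn = pd.read_csv(config.synonym_csv)
            synonyms = {faers_io.normalize_drug_name(r.reported_name):
                        faers_io.normalize_drug_name(r.normalized_name)
                        for r in syn.itertuples()}
        cases = faers_io.assemble_cases(demo, tables["DRUG"], tables["REAC"],
                                        tables["THER"], tables["OUTC"], synonyms)
        manifest["funnel"]["assembled_cases"] = len(cases)

        stage = "case_definition"
        smq = (case_definition.load_smq_csv(config.smq_csv) if config.smq_csv
               else datasets.load_alopecia_smq())
        event_ids = case_definition.flag_event_cases(cases, smq)
        index = case_definition.build_drug_case_index(cases, event_ids,
                                                      config.role_filter)
        manifest["funnel"]["event_cases"] = len(index.event_cases)
        manifest["funnel"]["drugs_with_event_reports"] = sum(
            1 for d in index.drug_cases
            if index.drug_cases[d] & index.event_cases)

        stage = "baseline"
        baseline = strat.baseline_summary(cases, event_ids)
        baseline.to_csv(out / "baseline.csv", index=False)
        manifest["outputs"]["baseline"] = "baseline.csv"

        stage = "signals"
        signals = disproportionality.signal_table(
            index, thresholds=config.thresholds(), min_cases=config.min_cases,
            mgps_seed=config.seed)
        signals.to_csv(out / "signals.csv", index=False)
        manifest["outputs"]["signals"] = "signals.csv"
        positives = signals.loc[signals["positive"], "drug_name"].tolist()
        manifest["funnel"]["positive_drugs"] = len(positives)

        stage = "exclusion"
        if config.exclusion_csv:
            excl = case_definition.load_drug_list_csv(config.exclusion_csv)
            excl_set = {e.upper() for e in excl}
            positives = [d for d in positives if d.upper() not in excl_set]
        manifest["funnel"]["positive_drugs_after_exclusion"] = len(positives)

        stage = "risk_tiers"
        ic_map = dict(zip(signals["drug_name"], signals["ic025"]))
        tiers, tier_counts = strat.classify_risk_tier(
            {d: ic_map[d] for d in positives})
        pd.DataFrame(sorted(tiers.items()), columns=["drug_name", "tier"]) \
            .to_csv(out / "risk_tiers.csv", index=False)
        manifest["outputs"]["risk_tiers"] = "risk_tiers.csv"
        manifest["tier_counts"] = tier_counts

        stage = "stratification"
        if config.stratify:
            per_stratum = strat.stratified_signals(
                cases, event_ids, DEFAULT_STRATA, config.role_filter,
                thresholds=config.thresholds(), min_cases=config.min_cases)
            frames = [df for df in per_stratum.values() if not df.empty]
            if frames:
                pd.concat(frames, ignore_index=True) \
                    .to_csv(out / "stratified_signals.csv", index=False)
                manifest["outputs"]["stratified_signals"] = "stratified_signals.csv"

        stage = "tto"
        tto_table = tto.per_drug_tto_table(cases, positives)
        tto_table.to_csv(out / "tto_summary.csv", index=False)
        manifest["outputs"]["tto"] = "tto_summary.csv"

        stage = "label_check"
        if config.label_csv:
            annotations = strat.load_label_annotations(config.label_csv)
            check = strat.label_crosscheck(positives, annotations)
            with open(out / "label_check.json", "w", encoding="utf-8") as fh:
                json.dump(check, fh, indent=2)
            manifest["outputs"]["label_check"] = "label_check.json"
            manifest["label_check"] = {k: check[k] for k in
                                       ("n_total", "documented_pct", "undocumented_pct")}
    except ValidationFailure:
        raise
    except Exception as exc:  # stage failure -> recorded, partial outputs kept
        logger.exception("pipeline failed at stage %s", stage)
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
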