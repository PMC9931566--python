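"""Run configuration and the end-to-end pipeline driver.

A single YAML-style config carries the study parameters (index rule, site
gates, top-K, detection algorithm, SDoH percentile pair, suppression
policy) and three seeds (generator / analysis / disclosure).  ``run_all``
chains synth -> cohort -> conet -> sdoh -> summaries and writes a manifest
with per-stage status, counts and output checksums; a rerun with the same
config and seeds is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import conet, io, sdoh, summaries, synth
from .cohort import (IndexRule, SiteCriteria, apply_exclusions,
                     derive_index, filter_sites, included, summarize,
                     window_events)
from .sdoh import SuppressionPolicy


class ValidationError(ValueError):
    """Configuration invalid; raised before any stage runs."""


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, with defaults matching the
    headline study parameters (index window Oct 1 2021 - May 26 2022,
    60-day analysis window, top-30 conditions, site gates 25%/75%/30 days,
    suppression below 20 with shifts up to 5)."""

    input_dir: str | None = None  # None -> generate synthetic input
    output_dir: str = "lcnet_out"
    index_code: str = "U09.9"
    window_start: str = "2021-10-01"
    window_end: str = "2022-05-26"
    window_days: int = 60
    min_lab_coverage: float = 0.25
    min_valid_end_dates: float = 0.75
    max_date_shift_days: int = 30
    top_k: int = 30
    algorithm: str = "louvain"
    resolution: float = 1.0
    sdoh_percentiles: tuple[float, float] = (100 / 3, 200 / 3)
    suppression_threshold: int = 20
    max_shift: int = 5
    n_patients: int = 3000
    generator_seed: int = 0
    analysis_seed: int = 0
    disclosure_seed: int = 0

    def validate(self) -> None:
        if pd.Timestamp(self.window_start) > pd.Timestamp(self.window_end):
            raise ValidationError("window_end before window_start")
        if self.window_days < 0:
            raise ValidationError("window_days must be non-negative")
        if self.top_k < 2:
            raise ValidationError("top_k must be at least 2")
        if self.algorithm not in ("louvain", "girvan_newman", "gn", "walktrap"):
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        lo, hi = self.sdoh_percentiles
        if not 0 <= lo < hi <= 100:
            raise ValidationError("sdoh_percentiles must satisfy 0<=lo<hi<=100")
        if self.suppression_threshold < 1 or self.max_shift < 1:
            raise ValidationError("suppression policy out of range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "sdoh_percentiles" in raw:
            raw["sdoh_percentiles"] = tuple(raw["sdoh_percentiles"])
        return cls(**raw)

    def index_rule(self) -> IndexRule:
        return IndexRule(code=self.index_code, window_start=self.window_start,
                         window_end=self.window_end,
                         window_days=self.window_days)

    def site_criteria(self) -> SiteCriteria:
        return SiteCriteria(min_lab_coverage=self.min_lab_coverage,
                            min_valid_end_dates=self.min_valid_end_dates,
                            max_date_shift_days=self.max_date_shift_days)


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the run manifest (also written to
    <output_dir>/run_manifest.json).  A stage failure aborts the run with
    the failing stage named; completed outputs are kept and the manifest is
    written with a FAILED marker."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": io.config_hash(config),
        "seeds": {"generator": config.generator_seed,
                  "analysis": config.analysis_seed,
                  "disclosure": config.disclosure_seed},
        "stages": {},
    }
    stage = "synth"
    try:
        if config.input_dir is None:
            gcfg = synth.GeneratorConfig(n_patients=config.n_patients,
                                         seed=config.generator_seed)
            tables = synth.generate_population(gcfg)
            io.write_tables(tables, out / "synth", seed=config.generator_seed,
                            config=gcfg)
        else:
            tables = io.read_tables(config.input_dir)
        manifest["stages"]["synth"] = {
            "status": "ok", "n_persons": int(len(tables.persons))}

        stage = "cohort"
        rule = config.index_rule()
        index = derive_index(tables.coded_events, rule)
        cohort = apply_exclusions(tables.persons, tables.visits, index,
                                  tables.tests)
        good_sites = filter_sites(tables.site_metadata,
                                  config.site_criteria())
        summary = summarize(cohort)
        windowed = window_events(cohort, tables.coded_events,
                                 config.window_days)
        inc = included(cohort)
        io.write_tables({"cohort": cohort,
                         "windowed_events": windowed},
                        out / "cohort", seed=config.analysis_seed)
        (out / "cohort" / "summary.json").write_text(
            json.dumps(summary.as_dict(), indent=2), encoding="utf-8")
        manifest["stages"]["cohort"] = {
            "status": "ok", "n_indexed": summary.n_initial,
            "n_excluded_inpatient_index": summary.n_excluded_inpatient_index,
            "n_base": summary.n_base, "eligible_sites": good_sites}

        stage = "conet"
        cond_events = windowed[windowed["event_class"] == "condition"]
        model = conet.CooccurrenceModel.from_events(cond_events, k=config.top_k)
        res = model.fit(algorithm=config.algorithm,
                        resolution=config.resolution,
                        seed=config.analysis_seed)
        strat = conet.stratified_networks(cohort, cond_events, k=config.top_k,
                                          algorithm=config.algorithm,
                                          resolution=config.resolution,
                                          seed=config.analysis_seed)
        conet_tables = {"edges": model.network.edge_list(),
                        "partition": res.membership_frame()}
        for group, r in strat.items():
            safe = group.replace("<", "lt").replace("+", "plus")
            conet_tables[f"partition_{safe}"] = r.membership_frame()
        io.write_tables(conet_tables, out / "conet", seed=config.analysis_seed)
        manifest["stages"]["conet"] = {
            "status": "ok", "Q": res.Q, "n_communities": res.n_communities,
            "strata": {g: r.n_communities for g, r in strat.items()}}

        stage = "sdoh"
        sdoh_vars = [c for c in tables.sdoh_by_zip.columns if c != "zip"]
        labels = {}
        for var in sdoh_vars:
            cat = sdoh.categorize_sdoh(tables.sdoh_by_zip, var,
                                       config.sdoh_percentiles)
            labels[var] = pd.Series(
                sdoh.label_patients(tables.persons, cat).values,
                index=tables.persons["person_id"])
        policy = SuppressionPolicy(threshold=config.suppression_threshold,
                                   max_shift=config.max_shift,
                                   seed=config.disclosure_seed)
        disclosure = sdoh.demographic_table(cohort, tables.persons,
                                            sdoh_labels=labels, policy=policy)
        io.write_tables({"demographics": disclosure.frame},
                        out / "sdoh", seed=config.disclosure_seed)
        manifest["stages"]["sdoh"] = {
            "status": "ok",
            "n_suppressed": int(disclosure.frame["suppressed"].sum()),
            "n_shifted": int(disclosure.frame["shifted"].sum())}

        stage = "summaries"
        procs = summaries.filter_informative_procedures(windowed)
        proc_table = summaries.categorize_procedures(procs, cohort)
        idx_series = inc.set_index("person_id")["index_date"]
        new_drugs = summaries.new_medications(
            tables.coded_events, idx_series, config.window_days)
        atc = summaries.atc_rollup(new_drugs, cohort)
        uptake = summaries.uptake_series(tables.coded_events)
        io.write_tables({"procedures": proc_table.frame,
                         "medications_atc3": atc,
                         "uptake": uptake.frame},
                        out / "summaries", seed=config.analysis_seed)
        manifest["stages"]["summaries"] = {
            "status": "ok",
            "n_procedure_rows": int(len(proc_table.frame)),
            "n_atc_rows": int(len(atc))}
    except Exception as exc:
        manifest["stages"][stage] = {"status": "FAILED", "error": str(exc)}
        (out / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str), encoding="utf-8")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str), encoding="utf-8")
    return manifest
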