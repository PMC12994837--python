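"""End-to-end orchestration: harmonize → resolve → classify → outcomes →
estimation → comparisons → optional disclosure protection.

A run is driven by a :class:`RunConfig` (usually loaded from YAML).  Inputs
are either file paths (EHR, census, events, covariates tables as delimited
text) or ``synthetic: true`` with generator settings.  Every stage writes
its tables under the output directory and the run ends with a manifest
recording the config digest, seed, row counts, dropped-record tallies and a
sha256 per output file — rerunning with the same config and seed reproduces
identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import categories, census_resolution, cohort_comparisons, concordance
from . import disclosure, estimation, outcomes as outcomes_mod, synthetic

__all__ = ["RunConfig", "StageError", "run_all", "build_records"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    output_dir: str = "concordkit_run"
    seed: int = 0
    synthetic: bool = True
    n_patients: int = 20_000
    ehr_path: str | None = None
    census_path: str | None = None
    events_path: str | None = None
    covariates_path: str | None = None
    mapping_path: str | None = None
    crosswalk_path: str | None = None
    allow_partial: bool = False
    strict_coding: bool = False
    top_k: int = 50
    exclude_prefixes: tuple = ("Z",)
    shift_family_size: int | None = None  # default: groups x outcomes actually run
    contrast_family_size: int = 39
    alpha_family: float = 0.05
    decennial_priority: bool = True
    disclosure_sigma: float | None = None  # None: no protection stage
    disclosure_base: int = 10
    focus_group: str = "NHPI"
    reference_group: str = "White"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise StageError("config", f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("ehr_path", "census_path", "events_path", "covariates_path"):
            p = getattr(cfg, name)
            if not cfg.synthetic and (p is None or not Path(p).exists()):
                raise StageError("config", f"{name} missing or does not exist: {p}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_records(
    ehr_labels: pd.DataFrame, census_labels: pd.DataFrame
) -> pd.DataFrame:
    """Join harmonized EHR labels with resolved census labels into records.

    Persons without a surviving census label fall out (the linked cohort
    requires valid census race/ethnicity); persons absent from the EHR table
    are not part of the registry and also fall out.
    """
    resolved = census_labels.dropna(subset=["census_races"])
    return ehr_labels.merge(
        resolved[["person_key", "census_category", "census_races"]],
        on="person_key",
        how="inner",
    )


def run_all(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": [],
        "outputs": {},
        "tallies": {},
        "complete": False,
    }

    def _emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=index)
        manifest["outputs"][name] = {
            "rows": int(len(df)),
            "sha256": _sha256(path),
        }

    def _stage(name: str):
        manifest["stages"].append(name)

    try:
        # -- inputs ---------------------------------------------------------
        _stage("inputs")
        if config.synthetic:
            cfg = synthetic.study_config(
                n_patients=config.n_patients, seed=config.seed
            )
            bundle = synthetic.generate(cfg)
            ehr, census = bundle.ehr, bundle.census
            events, covariates = bundle.events, bundle.covariates
            bundle.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
        else:
            try:
                ehr = pd.read_csv(config.ehr_path)
                census = pd.read_csv(config.census_path)
                events = pd.read_csv(config.events_path)
                covariates = pd.read_csv(config.covariates_path)
            except (FileNotFoundError, ValueError) as exc:
                raise StageError("inputs", str(exc)) from exc

        # -- harmonize ------------------------------------------------------
        _stage("harmonize")
        mapping = (
            categories.CodeMapping.from_csv(config.mapping_path)
            if config.mapping_path
            else categories.default_ehr_mapping()
        )
        unmapped: dict = {}
        try:
            ehr_labels = categories.harmonize_ehr_table(
                ehr, mapping, strict=config.strict_coding, unmapped_log=unmapped
            )
        except categories.CodingError as exc:
            raise StageError("harmonize", str(exc)) from exc
        manifest["tallies"]["unmapped_ehr_codes"] = unmapped
        _emit("ehr_labels", ehr_labels)

        # -- resolve --------------------------------------------------------
        _stage("census_resolution")
        required = {"person_key", "source", "year", "allocated", "hispanic", "races"}
        missing_cols = required - set(census.columns)
        if missing_cols:
            raise StageError(
                "census_resolution", f"census table missing columns {sorted(missing_cols)}"
            )
        census_labels = census_resolution.resolve_table(
            census, decennial_priority=config.decennial_priority
        )
        manifest["tallies"]["census_dropped_allocated"] = int(
            census_labels["n_dropped_allocated"].sum()
        )
        manifest["tallies"]["census_dropped_conflict"] = int(
            census_labels["n_dropped_conflict"].sum()
        )
        manifest["tallies"]["census_unresolved_persons"] = int(
            census_labels["census_races"].isna().sum()
        )
        _emit("census_labels", census_labels)

        # -- classify -------------------------------------------------------
        _stage("classify")
        records = build_records(ehr_labels, census_labels)
        records["status"] = concordance.classify_table(
            records, allow_partial=config.allow_partial
        )
        _emit("records", records)
        crosstab = concordance.build_crosstab(records)
        crosstab.to_csv(outdir / "crosstab")
        manifest["tallies"]["cohort_size"] = int(len(records))
        manifest["tallies"]["discordance_rate"] = concordance.discordance_rate(
            records, allow_partial=config.allow_partial
        )
        manifest["tallies"]["missingness_rate"] = concordance.missingness_rate(records)

        # -- outcomes -------------------------------------------------------
        _stage("outcomes")
        crosswalk = (
            outcomes_mod.Crosswalk.from_csv(config.crosswalk_path)
            if config.crosswalk_path
            else outcomes_mod.default_crosswalk()
        )
        unmapped_events: dict = {}
        matrix = outcomes_mod.ever_indicators(
            events,
            crosswalk,
            persons=records["person_key"],
            unmapped_log=unmapped_events,
        )
        manifest["tallies"]["unmapped_event_codes"] = unmapped_events
        top = outcomes_mod.top_k_outcomes(
            matrix, config.top_k, exclude_prefixes=config.exclude_prefixes
        )
        _emit("outcome_matrix", matrix.reset_index())
        manifest["tallies"]["top_outcomes"] = top

        # -- estimation -----------------------------------------------------
        _stage("estimation")
        ehr_lab = records.set_index("person_key")["ehr_category"]
        ehr_lab = ehr_lab[ehr_lab != categories.Category.UNREPORTED.value]
        census_lab = records.set_index("person_key")["census_category"]
        n_groups = census_lab.nunique()
        family = config.shift_family_size or (n_groups * len(top))
        alpha_adj = estimation.bonferroni_level(config.alpha_family, max(family, 1))
        prev = pd.concat(
            [
                estimation.group_prevalence(
                    ehr_lab, matrix, "EHR", alpha_adj, outcomes=top
                ),
                estimation.group_prevalence(
                    census_lab, matrix, "CENSUS", alpha_adj, outcomes=top
                ),
            ],
            ignore_index=True,
        )
        _emit("prevalence", prev)
        shifts = estimation.prevalence_shift_table(
            ehr_lab, census_lab, matrix, top,
            alpha_family=config.alpha_family, n_comparisons=family,
        )
        _emit("shifts", shifts)
        if top:
            focus = [
                (side, grp)
                for grp in (config.focus_group, config.reference_group)
                for side in ("EHR", "CENSUS")
            ]
            patterns = estimation.disaggregate_patterns(
                records, matrix[top[0]], focus, alpha_adj,
                allow_partial=config.allow_partial,
            )
            _emit("patterns", patterns)

        # -- comparisons ----------------------------------------------------
        _stage("comparisons")
        profiles = cohort_comparisons.band_covariates(covariates)
        contrasts = cohort_comparisons.demographic_contrasts(
            profiles, records,
            alpha_family=config.alpha_family,
            n_comparisons=config.contrast_family_size,
        )
        _emit("demographic_contrasts", contrasts)
        if "practice_key" in records.columns:
            summaries = cohort_comparisons.practice_summaries(records)
            _emit("practice_summaries", summaries)
            _emit("practice_regressions",
                  cohort_comparisons.practice_regressions(summaries))
            hispanic_pattern = (
                (records["ehr_category"] != "Hispanic")
                & (records["ehr_category"] != "Unreported")
                & (records["census_category"] == "Hispanic")
            )
            conc = cohort_comparisons.concentration_report(records, hispanic_pattern)
            manifest["tallies"]["hispanic_pattern_concentration"] = {
                k: v for k, v in conc.items() if k != "top_practices"
            }

        # -- disclosure (optional) -----------------------------------------
        if config.disclosure_sigma is not None:
            _stage("disclosure")
            noise = disclosure.NoiseConfig(
                sigma=config.disclosure_sigma,
                rounding_base=config.disclosure_base,
                seed=config.seed,
            )
            protected = disclosure.protect_counts(crosstab.counts, noise)
            _emit("crosstab_counts_protected", protected, index=True)

        manifest["complete"] = True
    finally:
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
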