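"""Shared fixtures: a small synthetic bundle and pipeline products."""

from __future__ import annotations

import importlib.util
import sys
from pathlib import Path

import pandas as pd
import pytest

from concordkit import categories, census_resolution, outcomes, pipeline, synthetic

REPO_ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def acceptance_mod():
    """The acceptance script, imported as a module (single source of truth
    for the published-count reconstruction)."""
    spec = importlib.util.spec_from_file_location(
        "acceptance_script", REPO_ROOT / "scripts" / "acceptance.py"
    )
    mod = importlib.util.module_from_spec(spec)
    sys.modules["acceptance_script"] = mod
    spec.loader.exec_module(mod)
    return mod


@pytest.fixture(scope="session")
def small_config() -> synthetic.SyntheticConfig:
    return synthetic.study_config(n_patients=8_000, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config) -> synthetic.SyntheticBundle:
    return synthetic.generate(small_config)


@pytest.fixture(scope="session")
def small_records(small_bundle) -> pd.DataFrame:
    ehr_labels = categories.harmonize_ehr_table(small_bundle.ehr)
    census_labels = census_resolution.resolve_table(small_bundle.census)
    records = pipeline.build_records(ehr_labels, census_labels)
    return records.merge(
        small_bundle.ehr[["person_key", "practice_key"]], on="person_key", how="left"
    ) if "practice_key" not in records.columns else records


@pytest.fixture(scope="session")
def small_matrix(small_bundle, small_records) -> pd.DataFrame:
    return outcomes.ever_indicators(
        small_bundle.events, persons=small_records["person_key"]
    )
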