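"""Shared fixtures: small simulated cohorts and a hand-rolled record builder."""

from __future__ import annotations

import pandas as pd
import pytest

from screencausal.records import FIELDS, CohortTable
from screencausal.simulate import SimulationConfig, simulate_cohort

RECORD_DEFAULTS = {
    "age_years": 58, "density_class": "nondense", "screening_round": "followup",
    "reader_set_id": "rs0", "reader1_id": "ra", "reader2_id": "rb",
    "supervised": 0, "reader1_used_ai": 0, "reader2_used_ai": 0,
    "study_group": "control", "ai_normal_tag": 0, "safety_net_triggered": 0,
    "safety_net_shown": pd.NA, "safety_net_accepted": pd.NA,
    "consensus": 0, "recall": 0, "biopsy": 0, "cancer_detected": 0,
    "invasiveness": "none", "stage": pd.NA, "grade": pd.NA, "size_class": pd.NA,
    "outcome_missing": 0, "cancelled": 0,
}


def make_table(rows: list[dict], provenance: str = "loaded") -> CohortTable:
    """Build a cohort table from sparse row dicts with sensible defaults."""
    full = []
    for i, row in enumerate(rows):
        rec = {"woman_id": f"w{i}", **RECORD_DEFAULTS, **row}
        full.append(rec)
    df = pd.DataFrame(full, columns=[f.name for f in FIELDS])
    for col in ("safety_net_shown", "safety_net_accepted", "age_years"):
        df[col] = pd.array(df[col], dtype="Int64")
    for col in ("supervised", "reader1_used_ai", "reader2_used_ai", "ai_normal_tag",
                "safety_net_triggered", "consensus", "recall", "biopsy",
                "cancer_detected", "outcome_missing", "cancelled"):
        df[col] = df[col].astype("int64")
    return CohortTable(df, provenance=provenance)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    # scaled-down study conditions: same rates, fewer women and reader sets
    return SimulationConfig(n_women=20_000, n_reader_sets=40, n_readers=30)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg, seed=1234)


@pytest.fixture(scope="session")
def mid_cohort():
    """Default (study-condition) configuration at moderate size."""
    cfg = SimulationConfig(n_women=120_000)
    return simulate_cohort(cfg, seed=2024)
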