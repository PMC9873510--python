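"""Shared fixtures: tiny hand-built cohorts and one default simulated cohort."""

from __future__ import annotations

import pandas as pd
import pytest

from atrodev import SimConfig, simulate_cohort
from atrodev.io_volumetry import COHORT_COLUMNS


def make_cohort(rows: list[dict]) -> pd.DataFrame:
    """Build a cohort table from sparse row dicts, filling common defaults."""
    defaults = {
        "field_strength": 3.0,
        "repetition_time": 2300.0,
        "inversion_time": 900.0,
    }
    frame = pd.DataFrame([{**defaults, **row} for row in rows])
    return frame[COHORT_COLUMNS]


def cohort_rows(
    subject_id: str,
    points: list[tuple[float, float, str]],
    region: str = "parahippocampal",
    scan_prefix: str | None = None,
    **acq,
) -> list[dict]:
    """Rows for one subject/region trajectory: (age, value, phase) triples."""
    prefix = scan_prefix or subject_id
    return [
        {
            "subject_id": subject_id,
            "scan_id": f"{prefix}_s{i + 1:02d}",
            "age_at_scan": age,
            "phase": phase,
            "region_label": region,
            "value": value,
            **acq,
        }
        for i, (age, value, phase) in enumerate(points)
    ]


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cohort, reused read-only across tests."""
    return simulate_cohort(SimConfig(seed=42))
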