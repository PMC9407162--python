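"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import datetime
import warnings

import pytest

from mssense.synthetic import CohortConfig, MissingnessConfig, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


SMALL_DATES = dict(
    study_start=datetime.date(2020, 1, 6),
    period_boundary=datetime.date(2020, 2, 3),
    study_end=datetime.date(2020, 3, 2),
)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Twelve participants over a 4+4 week window, no forced exclusions."""
    return CohortConfig(
        n_participants=12,
        seed=42,
        missingness=MissingnessConfig(
            daily_dropout=0.02, gap_rate=0.02, insufficient_fraction=0.0
        ),
        **SMALL_DATES,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    small_cohort.write(out)
    return out
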