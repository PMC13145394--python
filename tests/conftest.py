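"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from affectsense import blocks, synthetic

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_cohort():
    """12 participants, 14 days, default missingness; used by several suites."""
    cfg = synthetic.SyntheticConfig(n_participants=12, seed=7)
    return synthetic.inject_missingness(synthetic.generate_cohort(cfg))


@pytest.fixture(scope="session")
def small_datasets(small_cohort):
    ds, _ = blocks.build_dataset(small_cohort, "passive_only")
    dsps, _ = blocks.build_dataset(small_cohort, "with_PS")
    return {"passive_only": ds, "with_PS": dsps}


@pytest.fixture(scope="session")
def labels_cohort():
    """Label-statistics cohort: no coupling, iid residuals, no missingness."""
    cfg = synthetic.SyntheticConfig(
        n_participants=200, n_days=7, seed=11, mu=4.0,
        sigma_b=0.8, sigma_eps=0.5, rho=0.0, beta={},
        p_skip_beep=0.0, p_watch_off=0.0, p_gps_drop=0.0,
    )
    return synthetic.generate_cohort(cfg)


def make_gps_frame(latlon, times):
    """Helper: GPS DataFrame from coordinate and timestamp lists."""
    return pd.DataFrame({
        "timestamp": pd.to_datetime(times, utc=True),
        "lat": [p[0] for p in latlon],
        "lon": [p[1] for p in latlon],
    })


def offset_latlon(lat, lon, north_m, east_m):
    """Move a coordinate by meters (small-displacement approximation)."""
    return (lat + north_m / 111_320.0,
            lon + east_m / (111_320.0 * np.cos(np.radians(lat))))
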