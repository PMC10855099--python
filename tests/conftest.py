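"""Shared fixtures: the default-condition recovery run is computed once per
session and reused by the invariant and acceptance tests."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from claypmf.io import RunConfig
from claypmf.pipeline import run_pipeline

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def full_run(default_config):
    """Full synthetic recovery under the study conditions: 19 windows,
    2e5 retained samples each, seeds 42 + window index, 350 K, 1000 bins,
    1e-6 kcal/mol WHAM tolerance, 0.05 Å smoothing bandwidth."""
    return run_pipeline(default_config)
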