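"""Shared fixtures: a small synthetic city and a full pipeline run.

Session-scoped so the expensive artifacts (scene, truth, end-to-end
pipeline state) are built once and shared by the module and acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mslur.geo_io import RasterGrid
from mslur.pipeline import run_pipeline
from mslur.synthetic_city import (TruthParams, generate_scene,
                                  sample_observations, simulate_truth,
                                  study_dates, synthetic_config)


@pytest.fixture(scope="session")
def config():
    return synthetic_config(seed=0)


@pytest.fixture(scope="session")
def scene(config):
    return generate_scene(config)


@pytest.fixture(scope="session")
def dates(config):
    return study_dates(config)


@pytest.fixture(scope="session")
def truth(scene, dates):
    return simulate_truth(scene, TruthParams(), dates,
                          np.random.default_rng(1))


@pytest.fixture(scope="session")
def observations(truth, scene, dates):
    return sample_observations(truth, scene, TruthParams(), dates,
                               np.random.default_rng(2))


@pytest.fixture(scope="session")
def pipeline_state(tmp_path_factory):
    """Full end-to-end run on the seed-0 synthetic city."""
    out = tmp_path_factory.mktemp("run0")
    return run_pipeline(synthetic_config(seed=0), out_dir=out)


def flat_grid(n=20, value=0.0, cell=10.0, nodata=-9999.0):
    return RasterGrid(np.full((n, n), float(value)), 0.0, n * cell, cell,
                      crs="LOCAL", nodata=nodata)


@pytest.fixture
def grid20():
    return flat_grid(20)
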