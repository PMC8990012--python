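"""Shared fixtures.

The scaled parameter-recovery study (15 synthetic incidents, 56-profile
lattice, 50 replicates of 2 simulated hours on a 300x300 map) is the one
expensive computation in the suite; it runs once per session and is shared
by every test that needs a full end-to-end fit.
"""

import logging

import numpy as np
import pytest

import lostperson as lp
from lostperson.cli import run_fit_pipeline, run_loocv_pipeline, scaled_synthetic_study


@pytest.fixture
def flat_grid():
    """Open 200x200 map: constant elevation, no features, no water."""
    n = 200
    return lp.GridMap(
        np.zeros((n, n)), np.zeros((n, n), bool), np.zeros((n, n), bool)
    )


@pytest.fixture
def lake_grid():
    """60x60 flat map with a square lake east of the center."""
    n = 60
    inacc = np.zeros((n, n), bool)
    inacc[25:35, 40:50] = True
    feat = np.zeros((n, n), bool)
    feat[30, :] = True  # a trail through the middle
    feat &= ~inacc
    return lp.GridMap(np.zeros((n, n)), feat, inacc)


@pytest.fixture(scope="session")
def recovery_study(tmp_path_factory):
    """Full scaled recovery study: fit report plus LOOCV records."""
    logging.disable(logging.INFO)
    out = tmp_path_factory.mktemp("study")
    config = scaled_synthetic_study(seed=1, output_dir=str(out))
    report = run_fit_pipeline(config)
    records, summary = run_loocv_pipeline(config, report)
    logging.disable(logging.NOTSET)
    return {
        "config": config,
        "report": report,
        "records": records,
        "summary": summary,
    }
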