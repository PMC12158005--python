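"""Shared fixtures: seeded synthetic scenarios and multi-seed sweeps."""

from __future__ import annotations

import numpy as np
import pytest

from phasnet.config import RunConfig
from phasnet.evaluate import evaluate_run
from phasnet.pipeline import run_pipeline
from phasnet.simulate import SimParams, SyntheticDataset

N_SWEEP_SEEDS = 20


@pytest.fixture(scope="session")
def small_run():
    """One reduced-scale scenario run end to end (seed 1)."""
    ds = SyntheticDataset(SimParams.small(), 1)
    res = run_pipeline(ds)
    metrics = evaluate_run(ds, res, decoy_seed=1)
    return ds, res, metrics


@pytest.fixture(scope="session")
def sweep_metrics():
    """Recovery metrics across 20 seeded reduced-scale replicates."""
    out = []
    for seed in range(N_SWEEP_SEEDS):
        ds = SyntheticDataset(SimParams.small(), seed)
        res = run_pipeline(ds)
        out.append(evaluate_run(ds, res, decoy_seed=seed))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture()
def config():
    return RunConfig()
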