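from __future__ import annotations

import pytest

from spliceneo import PipelineConfig, SimulationConfig, run_synthetic_pipeline
from spliceneo import synthdata as sd


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline on the default synthetic study (fixed seed)."""
    return run_synthetic_pipeline(SimulationConfig(seed=11), PipelineConfig())


@pytest.fixture(scope="session")
def small_truth():
    """A small planted study used by per-module tests."""
    return sd.simulate_truth(SimulationConfig(seed=7, n_genes=12, n_events=12))


@pytest.fixture(scope="session")
def small_counts(small_truth):
    return sd.simulate_junction_counts(small_truth)
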