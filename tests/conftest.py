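"""Shared fixtures.

Simulation-backed fixtures are session-scoped: the fixture-scale library
(scale step 0.25, 3 beats) for fast unit tests, and the reduced-scale
library (step 0.05, 10 beats) that the acceptance checks share.
"""

from __future__ import annotations

import numpy as np
import pytest

from apdiff.ap_features import difference_dataset
from apdiff.cell_model import ModelParameters, StimulusProtocol, run_paced
from apdiff.classifier import MLPConfig, split_dataset, train
from apdiff.scan_generator import build_grid, generate_library


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def fixture_protocol() -> StimulusProtocol:
    return StimulusProtocol(n_beats=3)


@pytest.fixture(scope="session")
def standard_trace_fixture(params, fixture_protocol):
    """3-beat standard trace (fast, test scale only)."""
    return run_paced(params, fixture_protocol)


@pytest.fixture(scope="session")
def standard_trace_full(params):
    """Standard trace under the full 10-beat, CL-1000-ms protocol."""
    return run_paced(params, StimulusProtocol(n_beats=10))


@pytest.fixture(scope="session")
def fixture_library(fixture_protocol):
    """Scale step 0.25, 3 beats: 60 variants, suitable for unit tests."""
    return generate_library(build_grid(step=0.25), fixture_protocol,
                            step=0.25)


@pytest.fixture(scope="session")
def reduced_library():
    """Scale step 0.05, full 10-beat protocol: 380 variants."""
    return generate_library(build_grid(step=0.05), step=0.05)


@pytest.fixture(scope="session")
def reduced_dataset(reduced_library):
    return difference_dataset(reduced_library)


@pytest.fixture(scope="session")
def reduced_model(reduced_dataset):
    """Classifier trained on the 80% stratified split of the reduced grid."""
    cfg = MLPConfig(seed=0)
    train_set, test_set = split_dataset(reduced_dataset, cfg)
    model = train(train_set, cfg)
    return model, test_set


@pytest.fixture(scope="session")
def full_scan_apds(params):
    """Last-beat APD90 over the full 198-scale scan, for four channels.

    Channels: GKs (0), GKr (1), GCaL (5), GpK (9) — enough to check the
    published per-channel means and both directions of the
    significance-vs-standard pattern.
    """
    from apdiff.ap_features import measure_apd

    protocol = StimulusProtocol(n_beats=10)
    scales = np.concatenate([np.arange(1, 100), np.arange(101, 200)]) / 100.0
    out = {}
    for ch in (0, 1, 5, 9):
        apds = [measure_apd(run_paced(params.scaled(ch, float(s)), protocol))
                for s in scales]
        out[ch] = np.array([a for a in apds if np.isfinite(a)])
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
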