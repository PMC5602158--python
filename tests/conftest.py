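"""Shared fixtures: meshes and scenario runs are expensive, so they are
built once per session and shared across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from lnchemosim import (ModelConfig, build_mesh, run_scenario)

LOWRES = 2.0          # cells per 100 um for fast tests


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def mesh_lowres(config):
    return build_mesh(config.geometry, LOWRES)


@pytest.fixture(scope="session")
def mesh_default(config):
    return build_mesh(config.geometry, config.resolution)


class _ScenarioCache:
    """Runs each named scenario at the reduced resolution once."""

    def __init__(self):
        self._runs = {}

    def __call__(self, name: str, resolution: float = LOWRES):
        key = (name, resolution)
        if key not in self._runs:
            self._runs[key] = run_scenario(name, resolution=resolution)
        return self._runs[key]


@pytest.fixture(scope="session")
def scenario(config) -> _ScenarioCache:
    return _ScenarioCache()


@pytest.fixture(scope="session")
def baseline_lowres(scenario):
    return scenario("BASELINE_WT")


@pytest.fixture(scope="session")
def baseline_default(scenario, config):
    """The calibrated wild-type run at the default resolution."""
    return scenario("BASELINE_WT", resolution=config.resolution)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
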