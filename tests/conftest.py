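import numpy as np
import pytest

from digitizer_lab import (
    Condition, ModelParams, PlatformParams, SamplePopulation, Topology,
    UptakeParams,
)


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def platform() -> PlatformParams:
    return PlatformParams()


@pytest.fixture(scope="session")
def uptake() -> UptakeParams:
    return UptakeParams()


@pytest.fixture(scope="session")
def any_condition() -> Condition:
    return Condition(Topology.CONSTANT, flp_ng=35.0, shrna_ng=5.0,
                     dox_nM=225.0, time_h=48.0, replicate=0)


def make_population(values, channel="ofp", condition=None) -> SamplePopulation:
    """Population with one channel of interest; other channels set to 1."""
    values = np.asarray(values, float)
    cond = condition or Condition(Topology.CONSTANT, 35.0, 5.0, 225.0, 48.0)
    cols = {ch: np.ones_like(values) for ch in ("cfp", "ifp", "ofp")}
    cols[channel] = values
    return SamplePopulation.from_arrays(cond, **cols)


@pytest.fixture
def make_pop():
    return make_population
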