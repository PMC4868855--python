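"""Shared fixtures: seeded RNGs and session-scoped simulation runs.

The expensive network simulations are session-scoped and shared between the
engine tests and the acceptance battery, so each protocol is integrated
exactly once per test session.
"""

import dataclasses

import numpy as np
import pytest

from crstim.cli_io import make_fixture
from crstim.engine import SampleSet, run_protocol, run_samples
from crstim.stimulation import StimStage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_rvs_batch():
    """11 small-fixture samples: 20 s kindling, RVS CR at K=0.25 for 16 s, 16 s off."""
    cfg = make_fixture(
        "small", stages=[StimStage(mode="RVS", k=0.25, duration_s=16.0)], kindling_s=20.0
    )
    results = run_samples(cfg, SampleSet.default(11), raise_on_error=True)
    return cfg, results


@pytest.fixture(scope="session")
def small_svs_run():
    """One small-fixture sample driven by SVS CR at K=0.25 for 16 s."""
    cfg = make_fixture(
        "small", stages=[StimStage(mode="SVS", k=0.25, duration_s=16.0)], kindling_s=20.0
    )
    return cfg, run_protocol(cfg, 3, 4)


@pytest.fixture(scope="session")
def full_sham_run():
    """Full-scale network (N=200), 20 s kindling, then a 16 s sham (K=0) epoch.

    Doubles as the kindled-state reference: t = 0 is the end of kindling.
    """
    cfg = make_fixture(
        "full", stages=[StimStage(mode="RVS", k=0.0, duration_s=16.0)], kindling_s=20.0
    )
    return cfg, run_protocol(cfg, 1, 2)


@pytest.fixture(scope="session")
def tiny_cfg():
    """A very small, fast configuration for engine unit tests (N=16)."""
    from crstim.cli_io import RunConfig
    from crstim.engine import ProtocolTimeline
    from crstim.plasticity import TopologyParams
    from crstim.stimulation import StimGeometry, StimProtocol

    return RunConfig(
        topology=TopologyParams(n=16),
        geometry=StimGeometry(sites=(1, 5, 9, 13)),
        protocol=StimProtocol(stages=()),
        timeline=ProtocolTimeline(equilibration_s=0.2, kindling_s=1.0),
    )


def tiny_with_stage(tiny_cfg, stage, cr_off_s=None):
    from crstim.stimulation import StimProtocol

    return dataclasses.replace(
        tiny_cfg,
        protocol=StimProtocol(stages=(stage,), cr_off_s=cr_off_s),
    )
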