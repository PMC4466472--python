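"""Shared fixtures: a small synthetic study and the default full-size run.

Everything is generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from phasiforge.fold import default_backend
from phasiforge.pipeline import RunConfig, analyze
from phasiforge.synthetic_data import SimConfig, simulate_study

SMALL_YAML = """
seed: 5
sim:
  n_hairpins: 6
  n_pgt_initiator: 3
  n_pgt_cis: 1
  n_pgt_trans: 1
  depth_per_lib: 20000
  n_background_contigs: 6
"""


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def backend():
    return default_backend()


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    return RunConfig.from_yaml(SMALL_YAML)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config.sim)


@pytest.fixture(scope="session")
def small_result(small_config, small_study):
    return analyze(
        small_study.contigs,
        small_study.libraries,
        small_config,
        known_mirnas=small_study.manifest.known_mirnas,
    )


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    """The default synthetic study conditions (30 hairpins, 15 PGTs,
    3 libraries at 1e5 reads, seed 17)."""
    return RunConfig(seed=17)


@pytest.fixture(scope="session")
def default_study(default_config):
    return simulate_study(default_config.sim)


@pytest.fixture(scope="session")
def default_result(default_config, default_study):
    return analyze(
        default_study.contigs,
        default_study.libraries,
        default_config,
        known_mirnas=default_study.manifest.known_mirnas,
    )
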