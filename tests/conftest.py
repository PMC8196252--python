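"""Shared fixtures.

The spatial fixtures are session-scoped because scaled column runs take
tens of seconds each; every test that needs a control or variant run
shares the same three-replicate batch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cortigen import SimulationConfig, run
from cortigen.analysis import committed_alive, discard_above_mz, pool_position_tables

#: seeds of the replicate batch used by all spatial fixtures
REPLICATE_SEEDS = (1, 2, 3)


def run_batch(species: str, variant: str, seeds=REPLICATE_SEEDS, **overrides):
    return [run(SimulationConfig.scaled(species=species, variant=variant, seed=s, **overrides))
            for s in seeds]


def pooled_cells(results) -> pd.DataFrame:
    """Pooled, filtered position table of a replicate batch."""
    pooled = pool_position_tables([r.positions for r in results])
    return discard_above_mz(committed_alive(pooled))


def pooled_events(results) -> pd.DataFrame:
    return pd.concat([r.events for r in results], ignore_index=True)


@pytest.fixture(scope="session")
def human_control_runs():
    return run_batch("human_temporal", "control")


@pytest.fixture(scope="session")
def human_autism_runs():
    return run_batch("human_temporal", "autism_no_a2")


@pytest.fixture(scope="session")
def human_heterotopia_run():
    return run_batch("human_temporal", "heterotopia", seeds=(1,))


@pytest.fixture(scope="session")
def mouse_control_runs():
    return run_batch("mouse_barrel", "control")


# the polymicrogyria variants leave few cells per run (that is the
# phenotype), so their batches use six replicates; the runs are cheap
POLY_SEEDS = (1, 2, 3, 4, 5, 6)


@pytest.fixture(scope="session")
def mouse_poly_a1_runs():
    return run_batch("mouse_barrel", "polymicrogyria_a1", seeds=POLY_SEEDS)


@pytest.fixture(scope="session")
def mouse_poly_short_runs():
    return run_batch("mouse_barrel", "polymicrogyria_short", seeds=POLY_SEEDS)


@pytest.fixture(scope="session")
def quick_run_config():
    """A miniature column for fast determinism/plumbing tests."""
    return SimulationConfig.scaled(n_founders=16, symmetric_rounds=2, steps=500,
                                   domain_x=50.0, domain_y=50.0, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
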