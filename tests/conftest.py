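"""Shared fixtures: small networks and the session-scoped simulation batches.

The heavy experiment batches (control, plasticity-modulated, lesioned) are
built once per session and shared by the replay-statistics and
consolidation-property tests.  Batch sizes trade statistical power against
the runtime of a full 39-day simulation (a few seconds each).
"""

from __future__ import annotations

import numpy as np
import pytest

from tristage import RunConfig, run_simulation
from tristage.config import LesionSpec, ModulationSpec, scaled_half_life_ms
from tristage.consolidation import batch_seeds

N_CONTROL = 20
N_MODULATED = 20
N_ANTEROGRADE = 6
MASTER_SEED = 123

#: percepts 69-89 (patterns 205-267): the window probed by the modulation
#: experiments, evaluated 5 days after the modulated percept (day 35)
FACILITATION_IDS = list(range(205, 268))


def _batch(config: RunConfig, n: int) -> list:
    return [run_simulation(config, seed=s) for s in batch_seeds(MASTER_SEED, n)]


@pytest.fixture(scope="session")
def control_batch():
    """Default 39-day runs (plus a day-35 recall probe of percepts 69-89)."""
    return _batch(RunConfig(recall_days={35: FACILITATION_IDS}), N_CONTROL)


@pytest.fixture(scope="session")
def suppression_batch():
    """Runs with benzodiazepine-like HIP plasticity suppression at percept 89."""
    cfg = RunConfig(
        recall_days={35: FACILITATION_IDS},
        modulation=ModulationSpec(
            factor=0.1, onset_percept=89, half_life_ms=scaled_half_life_ms(7200.0)
        ),
    )
    return _batch(cfg, N_MODULATED)


@pytest.fixture(scope="session")
def boost_batch():
    """Runs with a x2 HIP plasticity boost while percept 89 is learned."""
    cfg = RunConfig(
        recall_days={35: FACILITATION_IDS},
        modulation=ModulationSpec(factor=2.0, onset_percept=89, half_life_ms=float("inf")),
    )
    return _batch(cfg, N_MODULATED)


@pytest.fixture(scope="session")
def anterograde_batch():
    """Runs with the whole hippocampus disabled before any learning."""
    cfg = RunConfig(lesion=LesionSpec(fraction=1.0, timing="before"))
    return _batch(cfg, N_ANTEROGRADE)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
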