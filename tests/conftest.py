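"""Shared fixtures: reduced-scale trained models for the three coding regimes.

The directional analyses compare models trained under balanced (STEC),
spatial-only (SEC) and temporal-only (TEC) objectives across several seeds.
Training is the expensive step, so one session-scoped fixture trains all
conditions at the reduced `smoke`-like scale (48 hidden units, minibatch
24, 2000 Adam iterations) and every analysis test reuses them.
"""

import numpy as np
import pytest

from stec.network import Architecture
from stec.objective import ObjectiveConfig, TrainingConfig, train

SEEDS = (0, 1, 2)
CONDITIONS = ("stec", "sec", "tec")

SMOKE_ARCH = Architecture(frame_shape=(64, 64), n_lower=48, n_upper=48)
SMOKE_ITERATIONS = 2000
SMOKE_MINIBATCH = 24


@pytest.fixture(scope="session")
def trained_models():
    """{(condition, seed): (params, loss_trace)} at the reduced scale."""
    models = {}
    for cond in CONDITIONS:
        for seed in SEEDS:
            trn = TrainingConfig(
                iterations_per_repetition=SMOKE_ITERATIONS,
                repetitions=1,
                minibatch=SMOKE_MINIBATCH,
                n_scenes=16,
                master_seed=seed,
                trace_every=100,
            )
            models[(cond, seed)] = train(
                ObjectiveConfig.from_preset(cond), trn, SMOKE_ARCH
            )
    return models


@pytest.fixture(scope="session")
def probe_batch():
    """A fixed batch of random gaze-like sequences for response statistics."""
    return np.random.default_rng(1234).random((12, 9, 64, 64))
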