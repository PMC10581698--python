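"""Shared fixtures.

The expensive session fixture trains the desk-preset model once under the
reference study conditions (constant Ne=10,000, 2 cM at a uniform
10^-8/bp/gen crossover rate, 20 haplotypes, 15 epochs); several tests reuse
it: held-out accuracy, transfer learning, and interpretability direction
checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from tmrcanet import (
    DemographicModel,
    SimulationConfig,
    TrainConfig,
    desk_config,
    simulate_dataset,
    train,
)

REFERENCE_NE = 10_000
REFERENCE_SIM = dict(n_haplotypes=20, region_length=2_000_000)


def reference_sim_config(seed: int = 0, **overrides) -> SimulationConfig:
    kwargs = dict(REFERENCE_SIM)
    kwargs.update(overrides)
    return SimulationConfig(
        DemographicModel.constant(REFERENCE_NE), seed=seed, **kwargs
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A cheap labelled dataset shared by read-only tests."""
    return simulate_dataset(reference_sim_config(seed=42, region_length=500_000, n_haplotypes=12))


@pytest.fixture(scope="session")
def trained_desk():
    """Desk-preset model trained under the reference conditions."""
    cfg = TrainConfig(
        sim=reference_sim_config(seed=0),
        model=desk_config(L=512),
        epochs=15,
        sims_per_epoch=64,
        val_sims=4,
        seed=11,
    )
    return train(cfg)


@pytest.fixture(scope="session")
def heldout_pairs(trained_desk):
    """Fresh simulations on seeds never used in training, with sampled pairs."""
    rng = np.random.default_rng(999)
    out = []
    for k in range(3):
        panel, labels = simulate_dataset(reference_sim_config(seed=1_000_000 + k))
        for _ in range(4):
            pick = rng.choice(panel.n_haplotypes, size=2, replace=False)
            out.append((panel, labels, (int(pick.min()), int(pick.max()))))
    return out
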