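"""Shared fixtures.

The expensive end-to-end fixture (`toy_benchmark`) trains the scaled-down
model once per session; everything downstream (completion accuracy,
generation diversity, condition-trend recovery) evaluates that single
trained model.
"""

from __future__ import annotations

import pytest

from cardio4d import (CohortSpec, ModelConfig, SequenceVAE,
                      generate_sequence, sample_conditions)
from cardio4d.experiments import ToyBenchmark, run_toy_benchmark


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    """Smallest legal configuration: fast mechanics checks only."""
    return ModelConfig(grid_shape=(16, 16, 16), n_frames=3, latent_dim=8,
                       encoder_channels=(2, 4, 8, 16),
                       condition_mlp_widths=(16,), batch_size=4,
                       max_epochs=3, early_stop_patience=2, seed=7)


@pytest.fixture(scope="session")
def tiny_model(tiny_config) -> SequenceVAE:
    return SequenceVAE(tiny_config)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    spec = CohortSpec(n_subjects=6, grid_shape=tiny_config.grid_shape,
                      n_frames=tiny_config.n_frames, seed=3)
    conds = sample_conditions(6, 3)
    seqs = [generate_sequence(c, spec, 900 + i) for i, c in enumerate(conds)]
    return list(zip(seqs, conds))


@pytest.fixture(scope="session")
def toy_benchmark() -> ToyBenchmark:
    """Train the desk-scale model once; shared by the end-to-end tests."""
    return run_toy_benchmark(seed=0)
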