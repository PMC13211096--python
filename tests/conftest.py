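"""Shared fixtures: synthetic datasets and the overfitting smoke run.

The smoke run (8 synthetic 96x96 patches, fixture encoder, 200 iterations)
is session-scoped because training takes ~1 minute and several tests probe
different aspects of the same run (convergence, loss trend, checkpointing).
"""

from __future__ import annotations

import numpy as np
import pytest

from weedseg.synthetic import FieldParams, generate_dataset
from weedseg.train import TrainConfig, train
from weedseg.unet import DecoderConfig

SMOKE_DATA_SEED = 7
SMOKE_TRAIN_SEED = 0


def smoke_field_params() -> FieldParams:
    """Field conditions for the CPU overfitting run: two crop rosettes and
    weeds thick enough (4-6 px) to be resolvable at the decoder's stride-4
    output resolution."""
    return FieldParams(
        extent=(96, 96), n_crops=2, crop_radius=14,
        weed_density=4.0, weed_length=(15, 30), weed_width=(4, 6),
        weed_blotch_frac=0.6, weed_blotch_radius=(4.0, 7.0))


def smoke_train_config(epochs: int = 200) -> TrainConfig:
    return TrainConfig(
        backbone="fixture_tiny", lr=1e-2, epochs=epochs, batch_size=8,
        seed=SMOKE_TRAIN_SEED, warmup_steps=20,
        decoder=DecoderConfig(64, (64, 48, 32)))


@pytest.fixture(scope="session")
def small_pairs():
    """Quick 64x64 synthetic patches for I/O and metric tests."""
    params = FieldParams(extent=(64, 64), n_crops=2, crop_radius=10,
                         weed_density=5.0, seed=3)
    pairs, _ = generate_dataset(6, params, seed=3)
    return pairs


@pytest.fixture(scope="session")
def smoke_pairs():
    pairs, _ = generate_dataset(8, smoke_field_params(), seed=SMOKE_DATA_SEED)
    return pairs


@pytest.fixture(scope="session")
def smoke_result(smoke_pairs):
    """One full 200-iteration overfitting run, shared across tests."""
    return train(smoke_train_config(), smoke_pairs, smoke_pairs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
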