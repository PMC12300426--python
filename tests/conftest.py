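"""Shared fixtures: small network/training configs and the one expensive
tiny-overfit run, computed once per session and reused by the capacity
smoke tests."""

import logging

import pytest

from caafseg import NetworkConfig, generate_dataset, pipeline
from caafseg.pipeline import TrainConfig

logging.getLogger("caafseg").setLevel(logging.ERROR)


def small_net_config(**overrides) -> NetworkConfig:
    """A reduced-scale architecture for fast training tests (32×32, 3 stages)."""
    kwargs = dict(input_size=32, stage_channels=(8, 16, 32), final_aspp=False,
                  attn_max_positions=256)
    kwargs.update(overrides)
    return NetworkConfig(**kwargs)


def clear_only_mix():
    return {"clear": 1.0, "small": 0.0, "adherent": 0.0, "cavitary": 0.0,
            "spiculated": 0.0}


@pytest.fixture(scope="session")
def overfit_run():
    """Default 64×64 model overfit on 8 clear-morphology fixtures.

    200 AdamW steps at a constant lr of 1e-4 (batch 4 → two steps per
    epoch × 100 epochs) with the Dice+Sobel composite; seeded and
    deterministic.
    """
    data = generate_dataset(8, clear_only_mix(), image_size=64, seed=7)
    cfg = TrainConfig(epochs=100, batch_size=4, lr=1e-4, loss_variant="sobel",
                      seed=7, eval_every=100, scheduler_step=1000)
    record, model = pipeline.train(cfg, data)
    return record, model, data
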