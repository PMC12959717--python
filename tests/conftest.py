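import numpy as np
import pytest

from maarnet.model import MAARNet, NetworkConfig
from maarnet.synthetic import SynthConfig, generate_sample
from maarnet.training import TrainConfig, train


def tiny_config(**overrides) -> NetworkConfig:
    """A small but structurally complete network for fast unit tests."""
    base = dict(stage_widths=(8, 16, 24, 32), stage_blocks=(1, 1, 1, 1),
                high_semantic_width=40, context_width=16,
                decoder_widths=(16, 24, 16, 12), final_width=8)
    base.update(overrides)
    return NetworkConfig(**base)


@pytest.fixture
def tiny_model():
    return MAARNet(tiny_config(), seed=0)


def overfit_fixture_config() -> NetworkConfig:
    """Desk-scale training configuration: the full architecture (every
    component enabled) at reduced widths, sized for minutes-long CPU runs."""
    return NetworkConfig(stage_widths=(16, 32, 48, 64), stage_blocks=(1, 1, 1, 1),
                         high_semantic_width=96, context_width=32,
                         decoder_widths=(32, 48, 48, 32), final_width=32)


def overfit_tiles(n: int = 8, tile_size: int = 128):
    cfg = SynthConfig(tile_size=tile_size, n_vessels=(3, 6),
                      vessel_width=(3.0, 8.0))
    return [generate_sample(cfg, 100 + i) for i in range(n)]


@pytest.fixture(scope="session")
def trained_model():
    """Full-architecture model overfit on 8 synthetic 128x128 tiles.

    Session-scoped: the same trained weights back the overfit-sanity,
    quantization-degradation and pruning-recovery checks.
    """
    data = overfit_tiles()
    model = MAARNet(overfit_fixture_config(), seed=0)
    train(model, data, TrainConfig(epochs=150, batch_size=4, seed=0,
                                   lr_decay_every=50, lr_decay=0.3,
                                   target_iou=0.95, check_every=10))
    return model, data
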