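import numpy as np
import pytest

import organotrack as ot


def small_scene_pairs(n, seed0):
    """(image, binary mask) pairs from 128x128 synthetic scenes."""
    pairs = []
    for i in range(n):
        spec = ot.FixtureSpec(image_size=128, n_organoids=4, radius_range=(10, 20),
                              min_gap=8, border_margin=6, seed=seed0 + i)
        img, labels, _ = ot.make_scene(spec)
        pairs.append((img, labels > 0))
    return pairs


@pytest.fixture(scope="session")
def trained_small_model():
    """A compact u-net (4 base filters, depth 3) trained on 50 synthetic
    128x128 scenes for up to 10 epochs; shared across tests that need a
    working detector."""
    train_pairs = small_scene_pairs(50, 1000)
    val_pairs = small_scene_pairs(8, 5000)
    net_cfg = ot.NetworkConfig(base_filters=4, depth=3, input_size=128)
    tr_cfg = ot.TrainingConfig(batch_size=2, max_epochs=10, patience=10, rng_seed=0)
    model, history = ot.train(train_pairs, val_pairs, net_cfg, tr_cfg)
    return model, history


@pytest.fixture(scope="session")
def heldout_scenes():
    """Held-out synthetic scenes (image, truth labels) never used in training."""
    scenes = []
    for i in range(10):
        spec = ot.FixtureSpec(image_size=128, n_organoids=4, radius_range=(10, 20),
                              min_gap=8, border_margin=6, seed=9000 + i)
        img, labels, _ = ot.make_scene(spec)
        scenes.append((img, labels))
    return scenes


def disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
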