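"""Architecture, preprocessing, augmentation and training contracts."""

import numpy as np
import pytest

import organotrack as ot
from organotrack import nn
from organotrack.evaluate import iou
from organotrack.unet import _prepare_batchable


def tally_parameters(base_filters: int, depth: int) -> int:
    """Independent layer-by-layer hand tally of kernel and bias counts for
    the u-net layout (paired 3x3 convs doubling from base_filters, 2x2
    transposed-conv up path with skip concatenation, 1x1 output conv)."""
    def conv(k, cin, cout):
        return k * k * cin * cout + cout

    total, cin = 0, 1
    for i in range(depth):                       # contracting path
        f = base_filters * 2 ** i
        total += conv(3, cin, f) + conv(3, f, f)
        cin = f
    fb = base_filters * 2 ** depth               # bottleneck
    total += conv(3, cin, fb) + conv(3, fb, fb)
    ch = fb
    for i in reversed(range(depth)):             # expanding path
        f = base_filters * 2 ** i
        total += conv(2, ch, f)                  # transposed conv 2x2
        total += conv(3, 2 * f, f) + conv(3, f, f)
        ch = f
    return total + conv(1, base_filters, 1)      # sigmoid head


def test_count_parameters_single_convolutions():
    count = lambda layer: sum(p.size for p in layer.params())
    assert count(nn.Conv2D(1, 1, 1)) == 2
    assert count(nn.Conv2D(1, 8, 3)) == 80  # 3*3*1*8 kernels + 8 biases


@pytest.mark.parametrize("base_filters,depth", [(8, 4), (4, 3), (16, 4), (64, 4)])
def test_count_parameters_matches_hand_tally(base_filters, depth):
    cfg = ot.NetworkConfig(base_filters=base_filters, depth=depth, input_size=2 ** depth * 16)
    net = ot.build_network(cfg)
    assert ot.count_parameters(net) == tally_parameters(base_filters, depth)


def test_parameter_count_monotone_in_width():
    counts = [ot.count_parameters(ot.build_network(ot.NetworkConfig(base_filters=f)))
              for f in (4, 8, 16, 32)]
    assert all(a < b for a, b in zip(counts, counts[1:]))


def test_parameter_scaling_law_quadratic_in_width():
    """Halving the first-layer width divides the parameter count by ~4
    (convolution weights scale quadratically in channel width)."""
    for f in (64, 32, 16):
        big = ot.count_parameters(ot.build_network(ot.NetworkConfig(base_filters=f)))
        small = ot.count_parameters(ot.build_network(ot.NetworkConfig(base_filters=f // 2)))
        assert 3.5 < big / small < 4.5


def test_invalid_input_size_rejected():
    with pytest.raises(ValueError):
        ot.NetworkConfig(input_size=100, depth=4)  # 100 not divisible by 16


def test_forward_output_shape_and_sigmoid_range():
    cfg = ot.NetworkConfig(base_filters=2, depth=2, input_size=32)
    net = ot.build_network(cfg, seed=0)
    z = net.forward(np.random.default_rng(0).normal(0, 1, (1, 32, 32, 1)).astype(np.float32))
    assert z.shape == (1, 32, 32, 1)
    p = nn.sigmoid(z)
    assert np.all((p > 0) & (p < 1))


def test_preprocess_resizes_and_rescales():
    rng = np.random.default_rng(0)
    cfg = ot.NetworkConfig(base_filters=2, depth=2, input_size=64)
    out = ot.preprocess(rng.uniform(0, 1000, (128, 128)), cfg)
    assert out.shape == (64, 64)
    assert 0.0 <= out.min() and out.max() <= 1.0


def test_preprocess_constant_image_is_all_zero():
    cfg = ot.NetworkConfig(base_filters=2, depth=2, input_size=32)
    assert not ot.preprocess(np.full((32, 32), 7.0), cfg).any()


def test_preprocess_identity_when_spanning_percentile_range():
    rng = np.random.default_rng(1)
    cfg = ot.NetworkConfig(base_filters=2, depth=2, input_size=64)
    img = rng.uniform(0, 1, (64, 64))
    out = ot.preprocess(img, cfg)
    lo, hi = np.percentile(img, [1, 99])
    expected = np.clip((img - lo) / (hi - lo), 0, 1)
    assert np.allclose(out, expected, atol=1e-6)


def test_predict_returns_original_resolution(trained_small_model):
    model, _ = trained_small_model
    prob = ot.predict(np.random.default_rng(0).uniform(0, 1, (80, 60)), model)
    assert prob.shape == (80, 60)
    assert prob.min() >= 0.0 and prob.max() <= 1.0


def test_predict_localises_blobs(trained_small_model, heldout_scenes):
    """A trained detector keeps spatial correspondence: the probability mass
    it assigns to each organoid sits on that organoid (centroid within 3 px)."""
    from scipy import ndimage as ndi
    model, _ = trained_small_model
    img, labels = heldout_scenes[0]
    prob = ot.predict(img, model)
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        cy, cx = ndi.center_of_mass(m)
        w = np.where(m, prob, 0.0)
        py, px = ndi.center_of_mass(w)
        assert np.hypot(py - cy, px - cx) < 3.0


def test_augment_contracts():
    rng = np.random.default_rng(0)
    pairs = [(rng.uniform(0, 1, (48, 48)), rng.random((48, 48)) > 0.7) for _ in range(5)]
    out = ot.augment(pairs, 50, seed=3)
    assert len(out) == 50
    for img, mask in out:
        assert img.shape == mask.shape == (48, 48)
        assert set(np.unique(mask)) <= {0, 1}
    out2 = ot.augment(pairs, 50, seed=3)
    for (a, am), (b, bm) in zip(out, out2):
        assert np.array_equal(a, b) and np.array_equal(am, bm)
    assert not np.array_equal(out[0][0], ot.augment(pairs, 50, seed=4)[0][0])


def test_augment_empty_input_rejected():
    with pytest.raises(ValueError):
        ot.augment([], 10)


def _tiny_sets():
    rng = np.random.default_rng(0)
    mk = lambda: (rng.uniform(0, 1, (16, 16)), rng.random((16, 16)) > 0.5)
    return [mk() for _ in range(4)], [mk() for _ in range(2)]


def test_early_stopping_patience_zero_with_flat_validation():
    """With patience 0 and a validation loss that never improves on the
    untrained baseline, training stops after a single epoch."""
    tr, val = _tiny_sets()
    cfg = ot.NetworkConfig(base_filters=2, depth=2, input_size=16, dropout_rate=0.0)
    tcfg = ot.TrainingConfig(patience=0, max_epochs=50, batch_size=2)
    model, hist = ot.train(tr, val, cfg, tcfg, val_loss_fn=lambda m: 1.0)
    assert len(hist["val_loss"]) == 1
    assert hist["best_epoch"] == 0  # baseline (initial weights) was best


def test_early_stopping_history_covers_patience_window():
    tr, val = _tiny_sets()
    cfg = ot.NetworkConfig(base_filters=2, depth=2, input_size=16, dropout_rate=0.0)
    tcfg = ot.TrainingConfig(patience=3, max_epochs=100, batch_size=2)
    # first value is the untrained baseline, then one per epoch
    losses = iter([0.5, 0.4, 0.45, 0.46, 0.47, 0.48, 0.49] + [0.6] * 100)
    model, hist = ot.train(tr, val, cfg, tcfg, val_loss_fn=lambda m: next(losses))
    assert hist["best_epoch"] == 1  # the 0.4 epoch
    assert len(hist["val_loss"]) == hist["best_epoch"] + tcfg.patience


def test_train_rejects_empty_sets():
    tr, val = _tiny_sets()
    cfg = ot.NetworkConfig(base_filters=2, depth=2, input_size=16)
    with pytest.raises(ValueError):
        ot.train([], val, cfg)
    with pytest.raises(ValueError):
        ot.train(tr, [], cfg)


def test_training_learns_synthetic_segmentation(trained_small_model, heldout_scenes):
    """The fixture-trained model clears the conventional IOU > 0.5 benchmark
    on held-out scenes (well above it on this easy synthetic task)."""
    model, hist = trained_small_model
    assert hist["val_loss"][-1] < hist["baseline_val_loss"]
    ious = [iou(ot.predict(img, model), labels > 0) for img, labels in heldout_scenes[:5]]
    assert min(ious) > 0.5


def test_mask_preparation_binarises_0_255():
    cfg = ot.NetworkConfig(base_filters=2, depth=2, input_size=16)
    img = np.zeros((16, 16))
    mask255 = np.zeros((16, 16), dtype=np.uint8)
    mask255[4:8, 4:8] = 255
    _, y = _prepare_batchable([(img, mask255)], cfg)
    assert set(np.unique(y)) == {0.0, 1.0}
    assert y.sum() == 16


def test_weight_checkpoint_round_trip(tmp_path):
    cfg = ot.NetworkConfig(base_filters=2, depth=2, input_size=32)
    net = ot.build_network(cfg, seed=5)
    path = tmp_path / "w.npz"
    net.save_weights(path)
    net2 = ot.load_model(path)
    x = np.random.default_rng(0).normal(0, 1, (1, 32, 32, 1)).astype(np.float32)
    assert np.array_equal(net.forward(x), net2.forward(x))
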