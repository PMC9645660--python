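"""Compact u-net for pixel-level organoid detection.

The network maps a single-channel microscopy image to a per-pixel organoid
probability map.  It follows the classic u-net layout — a contracting path of
paired 3x3 convolutions with 2x2 max-pooling, an expanding path of 2x2
transposed convolutions with skip concatenations, and a final 1x1 sigmoid
convolution — but with a drastically reduced channel width (8 first-layer
filters by default instead of the original 64), which keeps the trainable
parameter count below half a million while preserving segmentation quality on
organoid images and limiting overfitting on small training sets.

Hidden activations are ELU; dropout (rate 0.125) follows every convolution and
is active only during training.  Convolutions use "same" padding so the output
probability map has the same grid as the (resized) input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import nn
from .nn import F32


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters of the reduced u-net.

    base_filters
        Filter count of the first convolution level; doubles at each
        down-sampling level. Default 8.
    depth
        Number of 2x2 down-sampling levels; the bottleneck runs at
        ``base_filters * 2**depth`` channels. Default 4.
    input_size
        Side length (pixels) of the square network input; images are
        contrast-normalised and resized to this before inference. Default 512.
    dropout_rate
        Fraction of activations zeroed after each convolution during
        training. Default 0.125.
    """

    base_filters: int = 8
    depth: int = 4
    input_size: int = 512
    dropout_rate: float = 0.125
    activation_hidden: str = "elu"
    activation_output: str = "sigmoid"

    def __post_init__(self):
        if self.base_filters < 1 or self.depth < 1:
            raise ValueError("base_filters and depth must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.activation_hidden not in ("elu", "relu"):
            raise ValueError("activation_hidden must be 'elu' or 'relu'")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {2 ** self.depth}"
            )


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyperparameters (Adam + early stopping on validation loss)."""

    learning_rate: float = 0.001
    batch_size: int = 8
    patience: int = 10
    augmented_count: int = 2000
    max_epochs: int = 1000
    rng_seed: int = 0


class UNet:
    """A built (possibly untrained) u-net; also serves as its own description.

    ``layer_shapes`` lists every trainable layer as
    ``(name, kernel_shape, bias_shape)`` so the parameter count can be tallied
    independently of the weight arrays themselves.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(rng.integers(2 ** 31))
        f, d = config.base_filters, config.depth
        mk_drop = lambda: nn.Dropout(config.dropout_rate, self.dropout_rng)
        act = nn.ELU if config.activation_hidden == "elu" else nn.ReLU

        def conv_block(in_ch, out_ch):
            return [nn.Conv2D(in_ch, out_ch, 3, rng), act(), mk_drop(),
                    nn.Conv2D(out_ch, out_ch, 3, rng), act(), mk_drop()]

        self.down_blocks: list[list[nn.Layer]] = []
        self.pools: list[nn.MaxPool2x2] = []
        in_ch = 1
        for i in range(d):
            self.down_blocks.append(conv_block(in_ch, f * 2 ** i))
            self.pools.append(nn.MaxPool2x2())
            in_ch = f * 2 ** i
        self.bottleneck = conv_block(in_ch, f * 2 ** d)
        self.up_convs: list[nn.ConvTranspose2D] = []
        self.up_blocks: list[list[nn.Layer]] = []
        ch = f * 2 ** d
        for i in reversed(range(d)):
            fi = f * 2 ** i
            self.up_convs.append(nn.ConvTranspose2D(ch, fi, rng))
            self.up_blocks.append(conv_block(2 * fi, fi))
            ch = fi
        self.head = nn.Conv2D(f, 1, 1, rng)

    # ---- flat views over layers/parameters -------------------------------

    def _layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for blk in self.down_blocks:
            out.extend(blk)
        out.extend(self.bottleneck)
        for up, blk in zip(self.up_convs, self.up_blocks):
            out.append(up)
            out.extend(blk)
        out.append(self.head)
        return out

    def params(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads()]

    @property
    def layer_shapes(self) -> list[tuple[str, tuple, tuple]]:
        out = []
        for layer in self._layers():
            if isinstance(layer, (nn.Conv2D, nn.ConvTranspose2D)):
                out.append((type(layer).__name__, layer.W.shape, layer.b.shape))
        return out

    # ---- forward / backward ---------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch x of shape (n, h, w, 1); h, w divisible by 2^depth."""
        skips = []
        for blk, pool in zip(self.down_blocks, self.pools):
            for layer in blk:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        self._skip_channels = []
        for up, blk, skip in zip(self.up_convs, self.up_blocks, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            for layer in blk:
                x = layer.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.head.backward(dy)
        dskips = []
        for up, blk, c_skip in zip(reversed(self.up_convs), reversed(self.up_blocks),
                                   reversed(self._skip_channels)):
            for layer in reversed(blk):
                dy = layer.backward(dy)
            dskips.append(dy[..., :c_skip])
            dy = up.backward(dy[..., c_skip:])
        for layer in reversed(self.bottleneck):
            dy = layer.backward(dy)
        # dskips were collected shallow-first; down blocks unwind deep-first
        for blk, pool, dskip in zip(reversed(self.down_blocks), reversed(self.pools),
                                    reversed(dskips)):
            dy = pool.backward(dy) + dskip
            for layer in reversed(blk):
                dy = layer.backward(dy)

    # ---- persistence -----------------------------------------------------

    def save_weights(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params())}
        np.savez(path, depth=self.config.depth, base_filters=self.config.base_filters,
                 input_size=self.config.input_size, dropout_rate=self.config.dropout_rate,
                 **arrays)

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]


def load_model(path) -> UNet:
    """Rebuild a network from an .npz checkpoint written by ``save_weights``."""
    with np.load(path) as z:
        cfg = NetworkConfig(base_filters=int(z["base_filters"]), depth=int(z["depth"]),
                            input_size=int(z["input_size"]),
                            dropout_rate=float(z["dropout_rate"]))
        model = build_network(cfg)
        model.set_weights([z[f"p{i}"] for i in range(len(model.params()))])
    return model


def build_network(config: NetworkConfig = NetworkConfig(), seed: int = 0) -> UNet:
    """Build the (untrained, He-initialised) reduced u-net."""
    return UNet(config, seed=seed)


def count_parameters(spec: UNet) -> int:
    """Number of trainable scalar weights (kernels + biases)."""
    return int(sum(p.size for p in spec.params()))


def preprocess(image: np.ndarray, config: NetworkConfig = NetworkConfig()) -> np.ndarray:
    """Contrast-normalise and resize an image for the network.

    The 1st-99th intensity percentiles are rescaled to [0, 1] (robust to hot
    pixels), values are clipped, and the image is resized bilinearly to
    ``input_size`` square.  A constant image maps to all zeros.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    lo, hi = np.percentile(image, [1.0, 99.0])
    if hi - lo <= 0:
        out = np.zeros_like(image)
    else:
        out = np.clip((image - lo) / (hi - lo), 0.0, 1.0)
    s = config.input_size
    if out.shape != (s, s):
        out = resize(out, (s, s), order=1, anti_aliasing=out.shape[0] > s, clip=True)
    return out.astype(F32)


def predict(image: np.ndarray, model: UNet) -> np.ndarray:
    """Per-pixel organoid probability map at the original image resolution.

    The image is preprocessed to the network's input size, passed through the
    network (dropout off), and the sigmoid output is resized bilinearly back to
    the source grid so downstream area filters operate in original pixels.
    """
    orig_shape = np.asarray(image).shape
    x = preprocess(image, model.config)[None, :, :, None]
    logits = model.forward(x, train=False)[0, :, :, 0]
    prob = nn.sigmoid(logits)
    if prob.shape != orig_shape:
        prob = resize(prob, orig_shape, order=1, clip=True)
    return np.clip(prob, 0.0, 1.0)


def _random_transform(shape, rng):
    """A random rotation+zoom+shear affine about the image centre plus an
    elastic displacement field; returns a coordinate map for warping."""
    from scipy.ndimage import gaussian_filter

    h, w = shape
    angle = rng.uniform(-np.pi, np.pi)
    zoom = rng.uniform(0.9, 1.1)
    shear = rng.uniform(-0.15, 0.15)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    c, s = np.cos(angle), np.sin(angle)
    # rotation @ shear, scaled
    m = np.array([[c, -s], [s, c]]) @ np.array([[1.0, shear], [0.0, 1.0]]) / zoom
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    ry, rx = rows - cy, cols - cx
    src_r = m[0, 0] * ry + m[0, 1] * rx + cy
    src_c = m[1, 0] * ry + m[1, 1] * rx + cx
    # elastic: smoothed random displacement, a few pixels in amplitude
    alpha, sigma = 12.0, 8.0
    dr = gaussian_filter(rng.uniform(-1, 1, size=shape), sigma) * alpha
    dc = gaussian_filter(rng.uniform(-1, 1, size=shape), sigma) * alpha
    return src_r + dr, src_c + dc


def augment(pairs: list[tuple[np.ndarray, np.ndarray]], n: int,
            seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Produce ``n`` augmented (image, mask) pairs by random rotation, zoom,
    shear and elastic distortion; the identical geometric transform is applied
    to an image and its mask, and masks stay binary (nearest-neighbour warp).
    """
    from scipy.ndimage import map_coordinates

    if not pairs:
        raise ValueError("augment requires at least one (image, mask) pair")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        img, mask = pairs[rng.integers(len(pairs))]
        img = np.asarray(img, dtype=np.float64)
        mask = (np.asarray(mask) > 0).astype(np.uint8)
        if img.shape != mask.shape:
            raise ValueError("image and mask shapes differ")
        coords = _random_transform(img.shape, rng)
        wimg = map_coordinates(img, coords, order=1, mode="reflect")
        wmask = map_coordinates(mask, coords, order=0, mode="reflect")
        out.append((wimg.astype(F32), wmask.astype(np.uint8)))
    return out


def _prepare_batchable(pairs, config):
    """Resize (image, mask) pairs to the network input grid; masks become {0,1}."""
    xs, ys = [], []
    s = config.input_size
    for img, mask in pairs:
        xs.append(preprocess(img, config))
        m = (np.asarray(mask) > 0).astype(np.float64)
        if m.shape != (s, s):
            m = resize(m, (s, s), order=0, anti_aliasing=False)
        ys.append((m > 0.5).astype(F32))
    return np.stack(xs)[..., None], np.stack(ys)[..., None]


def _dataset_loss(model: UNet, x: np.ndarray, y: np.ndarray, batch: int = 8) -> float:
    tot, npix = 0.0, 0
    for i in range(0, len(x), batch):
        z = model.forward(x[i:i + batch], train=False)
        loss, _ = nn.bce_with_logits(z, y[i:i + batch])
        tot += loss * z.size
        npix += z.size
    return tot / npix


def train(train_set, val_set, net_config: NetworkConfig = NetworkConfig(),
          train_config: TrainingConfig = TrainingConfig(),
          val_loss_fn=None) -> tuple[UNet, dict]:
    """Train the u-net with Adam on unweighted binary cross-entropy.

    Early stopping monitors validation loss: the initial (untrained) weights
    set an epoch-0 baseline, and training halts once ``max(patience, 1)``
    consecutive epochs pass without strict improvement (or at ``max_epochs``).
    Returns the model restored to its best-validation-epoch weights, and a
    history dict with per-epoch train/validation losses and the best epoch.

    ``val_loss_fn(model) -> float`` may be supplied to override how validation
    loss is computed (e.g. on a streamed dataset).
    """
    if not train_set:
        raise ValueError("empty training set")
    if not val_set and val_loss_fn is None:
        raise ValueError("empty validation set: early stopping undefined")
    xt, yt = _prepare_batchable(train_set, net_config)
    if val_loss_fn is None:
        xv, yv = _prepare_batchable(val_set, net_config)
        val_loss_fn = lambda m: _dataset_loss(m, xv, yv, train_config.batch_size)

    model = build_network(net_config, seed=train_config.rng_seed)
    opt = nn.Adam(model.params(), lr=train_config.learning_rate)
    shuffle_rng = np.random.default_rng(train_config.rng_seed + 1)

    best_val = val_loss_fn(model)
    best_weights = model.get_weights()
    best_epoch = 0
    history = {"train_loss": [], "val_loss": [], "baseline_val_loss": best_val}
    stall = 0
    for epoch in range(1, train_config.max_epochs + 1):
        order = shuffle_rng.permutation(len(xt))
        ep_loss, nb = 0.0, 0
        for i in range(0, len(order), train_config.batch_size):
            idx = order[i:i + train_config.batch_size]
            z = model.forward(xt[idx], train=True)
            loss, dz = nn.bce_with_logits(z, yt[idx])
            model.backward(dz)
            opt.step(model.grads())
            ep_loss += loss
            nb += 1
        vloss = val_loss_fn(model)
        history["train_loss"].append(ep_loss / max(nb, 1))
        history["val_loss"].append(vloss)
        if vloss < best_val:
            best_val = vloss
            best_weights = model.get_weights()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
        if stall >= max(train_config.patience, 1):
            break
    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    return model, history
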