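"""Encoder--decoder segmentation network, training loop and tiled inference.

The architecture is a U-Net: each depth holds two convolution layers, each
followed by batch normalization and parametric ReLU; downsampling uses
stride-2 max pooling, upsampling nearest-neighbour doubling followed by a
convolution, with skip connections concatenated channel-wise.  The full
configuration uses six depths with 16, 32, 64, 128, 256 and 512 filters and
512-pixel input patches; training uses Dice loss with the Adam optimizer at
learning rate 1e-3.  A reduced three-depth 8/16/32 variant is provided for
CPU-scale experiments and is what the test suite trains.

Training is fully seeded (weight init, shuffling, augmentation draws all
come from one :class:`numpy.random.Generator`), so identical seeds and data
give bit-identical metric logs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from gratio.mask import AXON, MYELIN, LabelMask
from gratio.segmentation.nn import (
    Adam,
    BatchNorm2D,
    Conv2D,
    MaxPool2,
    Param,
    PReLU,
    Sequential,
    UpsampleNearest2,
    dice_loss_and_grad,
    softmax,
)

N_CLASSES = 3

DEFAULT_AUGMENTATIONS = frozenset({"rotate", "flip", "zoom", "gaussian_noise", "gaussian_smooth"})


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration.

    ``depths`` are the filter counts per level (strictly increasing);
    ``patch_size`` must be divisible by ``2**(levels-1)`` so the pooling
    path stays aligned.  Defaults reproduce the full-scale setup; pass
    ``reduced()`` for the CPU-scale variant.
    """

    depths: tuple[int, ...] = (16, 32, 64, 128, 256, 512)
    patch_size: int = 512
    stride: int = 2
    learning_rate: float = 1e-3
    loss: str = "dice"
    optimizer: str = "adam"
    augmentations: frozenset = DEFAULT_AUGMENTATIONS
    epochs: int = 20
    batch_size: int = 2
    val_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if len(self.depths) < 2 or any(
            b <= a for a, b in zip(self.depths, self.depths[1:])
        ):
            raise ValueError("depths must be strictly increasing with >= 2 levels")
        if self.patch_size % (2 ** (len(self.depths) - 1)) != 0:
            raise ValueError("patch_size must be a multiple of 2**(levels-1)")
        if self.stride != 2:
            raise ValueError("only stride 2 is supported")
        unknown = set(self.augmentations) - DEFAULT_AUGMENTATIONS
        if unknown:
            raise ValueError(f"unknown augmentations: {sorted(unknown)}")

    @staticmethod
    def reduced(**overrides) -> "TrainConfig":
        """Three-depth 8/16/32 variant for CPU-scale training."""
        defaults = dict(
            depths=(8, 16, 32),
            patch_size=256,
            epochs=25,
            augmentations=frozenset({"flip", "rotate"}),
        )
        defaults.update(overrides)
        return TrainConfig(**defaults)


def _conv_block(c_in: int, c_out: int, rng: np.random.Generator) -> Sequential:
    return Sequential(
        [
            Conv2D(c_in, c_out, 3, rng),
            BatchNorm2D(c_out),
            PReLU(c_out),
            Conv2D(c_out, c_out, 3, rng),
            BatchNorm2D(c_out),
            PReLU(c_out),
        ]
    )


class UNet:
    """U-Net over single-channel images producing 3-class logits."""

    def __init__(self, config: TrainConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.config = config
        f = config.depths
        levels = len(f)
        self.enc = [_conv_block(1 if i == 0 else f[i - 1], f[i], rng) for i in range(levels)]
        self.pools = [MaxPool2() for _ in range(levels - 1)]
        self.ups = [UpsampleNearest2() for _ in range(levels - 1)]
        # channel-halving convolution after each upsample, then the merge block
        self.upconvs = [
            Sequential([Conv2D(f[i + 1], f[i], 3, rng), BatchNorm2D(f[i]), PReLU(f[i])])
            for i in reversed(range(levels - 1))
        ]
        self.dec = [_conv_block(2 * f[i], f[i], rng) for i in reversed(range(levels - 1))]
        self.final = Conv2D(f[0], N_CLASSES, 1, rng)
        self._skip_channels: list[int] = []

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for block in [*self.enc, *self.upconvs, *self.dec, self.final]:
            out.extend(block.params())
        return out

    @property
    def levels(self) -> int:
        return len(self.config.depths)

    @property
    def divisor(self) -> int:
        return 2 ** (self.levels - 1)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected input of shape (N, 1, H, W)")
        if x.shape[2] % self.divisor or x.shape[3] % self.divisor:
            raise ValueError(f"spatial dims must be multiples of {self.divisor}")
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block.forward(h, train=train)
            if i < self.levels - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train=train)
        self._skip_channels = [s.shape[1] for s in skips]
        for j in range(self.levels - 1):
            h = self.ups[j].forward(h, train=train)
            h = self.upconvs[j].forward(h, train=train)
            h = np.concatenate([h, skips[-1 - j]], axis=1)
            h = self.dec[j].forward(h, train=train)
        return self.final.forward(h, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.final.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * (self.levels - 1)
        for j in reversed(range(self.levels - 1)):
            dy = self.dec[j].backward(dy)
            c = dy.shape[1] - self._skip_channels[-1 - j]
            dy, dskip = dy[:, :c], dy[:, c:]
            dskips[-1 - j] = dskip
            dy = self.upconvs[j].backward(dy)
            dy = self.ups[j].backward(dy)
        for i in reversed(range(self.levels)):
            if i < self.levels - 1:
                dy = self.pools[i].backward(dy)
                dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)


# -- persistence -------------------------------------------------------------


def save_model(model: UNet, path: str | Path) -> None:
    """Serialize weights, batch-norm running stats and config to one .npz."""
    path = Path(path)
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    bn_i = 0
    for layer in _iter_layers(model):
        if isinstance(layer, BatchNorm2D):
            arrays[f"bn_mean_{bn_i}"] = layer.running_mean
            arrays[f"bn_var_{bn_i}"] = layer.running_var
            bn_i += 1
    cfg = asdict(model.config)
    cfg["augmentations"] = sorted(cfg["augmentations"])
    arrays["config_json"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> UNet:
    with np.load(Path(path)) as data:
        cfg = json.loads(bytes(data["config_json"].tobytes()).decode())
        cfg["depths"] = tuple(cfg["depths"])
        cfg["augmentations"] = frozenset(cfg["augmentations"])
        model = UNet(TrainConfig(**cfg))
        for i, p in enumerate(model.params()):
            p.value = data[f"param_{i}"]
        bn_i = 0
        for layer in _iter_layers(model):
            if isinstance(layer, BatchNorm2D):
                layer.running_mean = data[f"bn_mean_{bn_i}"]
                layer.running_var = data[f"bn_var_{bn_i}"]
                bn_i += 1
    return model


def _iter_layers(model: UNet):
    for block in [*model.enc, *model.upconvs, *model.dec]:
        yield from block.layers
    yield model.final


# -- data augmentation --------------------------------------------------------


def _augment(
    image: np.ndarray, labels: np.ndarray, kinds: frozenset, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly augment an image/label pair; labels use nearest interpolation."""
    if "flip" in kinds:
        if rng.random() < 0.5:
            image, labels = image[::-1], labels[::-1]
        if rng.random() < 0.5:
            image, labels = image[:, ::-1], labels[:, ::-1]
    if "rotate" in kinds:
        k = int(rng.integers(0, 4))
        if k:
            image, labels = np.rot90(image, k), np.rot90(labels, k)
        angle = float(rng.uniform(-15.0, 15.0))
        image = ndimage.rotate(image, angle, reshape=False, order=1, mode="reflect")
        labels = ndimage.rotate(labels, angle, reshape=False, order=0, mode="reflect")
    if "zoom" in kinds:
        z = float(rng.uniform(0.9, 1.1))
        image = _zoom_keep_shape(image, z, order=1)
        labels = _zoom_keep_shape(labels, z, order=0)
    if "gaussian_noise" in kinds and rng.random() < 0.5:
        image = np.clip(image + rng.normal(0.0, 0.03, image.shape), 0.0, 1.0)
    if "gaussian_smooth" in kinds and rng.random() < 0.5:
        image = ndimage.gaussian_filter(image, sigma=float(rng.uniform(0.3, 1.0)))
    return np.ascontiguousarray(image), np.ascontiguousarray(labels)


def _zoom_keep_shape(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    h, w = arr.shape
    zoomed = ndimage.zoom(arr, factor, order=order, mode="reflect")
    zh, zw = zoomed.shape
    if zh >= h:  # center crop
        r0, c0 = (zh - h) // 2, (zw - w) // 2
        return zoomed[r0 : r0 + h, c0 : c0 + w]
    out = np.zeros_like(arr)  # center pad with edge reflection omitted: pad with border value
    r0, c0 = (h - zh) // 2, (w - zw) // 2
    out[...] = zoomed[0, 0]
    out[r0 : r0 + zh, c0 : c0 + zw] = zoomed
    return out


# -- training -----------------------------------------------------------------


def _onehot(labels: np.ndarray) -> np.ndarray:
    return np.stack([(labels == c).astype(np.float64) for c in range(N_CLASSES)])


def _dice_of_class(pred: np.ndarray, truth: np.ndarray, code: int) -> float:
    a, b = pred == code, truth == code
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def train(
    images: list[np.ndarray],
    masks: list[LabelMask],
    config: TrainConfig,
) -> tuple[UNet, list[dict]]:
    """Train the network; returns the model and a per-epoch metric log.

    The pairs are split into a training and a validation set by
    ``config.val_fraction`` (at least one pair is kept for training); each
    log entry records the epoch's mean training loss and the validation
    Dice of axon and myelin computed from argmax predictions.  With no
    validation pair the Dice entries are NaN.
    """
    if not images:
        raise ValueError("empty training set")
    if len(images) != len(masks):
        raise ValueError("images and masks must align")
    label_arrays = [m.labels if isinstance(m, LabelMask) else np.asarray(m) for m in masks]
    for img, lab in zip(images, label_arrays):
        if img.shape != lab.shape:
            raise ValueError("image/mask shape mismatch")

    rng = np.random.default_rng(config.seed)
    model = UNet(config, rng=rng)
    opt = Adam(model.params(), lr=config.learning_rate)

    n = len(images)
    n_val = min(int(round(config.val_fraction * n)), n - 1)
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]

    log: list[dict] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start : start + config.batch_size]
            xs, ts = [], []
            for i in batch:
                img, lab = _augment(images[i], label_arrays[i], config.augmentations, rng)
                xs.append(img[None])
                ts.append(_onehot(lab))
            x = np.stack(xs).astype(np.float64)
            t = np.stack(ts)
            opt.zero_grad()
            logits = model.forward(x, train=True)
            loss, dz = dice_loss_and_grad(logits, t)
            model.backward(dz)
            opt.step()
            losses.append(loss)
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_dice_axon": float("nan"),
            "val_dice_myelin": float("nan"),
        }
        if len(val_idx):
            da, dm = [], []
            for i in val_idx:
                pred = predict(images[i], model).argmax_labels()
                da.append(_dice_of_class(pred, label_arrays[i], AXON))
                dm.append(_dice_of_class(pred, label_arrays[i], MYELIN))
            entry["val_dice_axon"] = float(np.mean(da))
            entry["val_dice_myelin"] = float(np.mean(dm))
        log.append(entry)
    return model, log


# -- inference ----------------------------------------------------------------


def _forward_whole(model: UNet, image: np.ndarray) -> np.ndarray:
    """Single forward pass with reflect-padding to the pooling divisor."""
    d = model.divisor
    h, w = image.shape
    ph, pw = (-h) % d, (-w) % d
    x = np.pad(image, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else image
    logits = model.forward(x[None, None].astype(np.float64), train=False)
    return softmax(logits, axis=1)[0, :, :h, :w]


def _tile_window(tile: int, overlap: int) -> np.ndarray:
    """2-D blending weights: flat interior, cosine ramp over the overlap."""
    w1 = np.ones(tile)
    if overlap > 0:
        ramp = 0.5 - 0.5 * np.cos(np.pi * (np.arange(overlap) + 0.5) / overlap)
        w1[:overlap] = ramp
        w1[-overlap:] = ramp[::-1]
    w1 = np.maximum(w1, 1e-3)
    return np.outer(w1, w1)


def predict(
    image: np.ndarray,
    model: UNet,
    tile: int | None = None,
    overlap: int = 0,
) -> "ProbabilityMaps":
    """Predict class probabilities, tiling large images with blended overlaps."""
    from gratio.segmentation import ProbabilityMaps  # local import avoids a cycle

    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:  # RGB to luminance
        image = image.mean(axis=2)
    if image.ndim != 2 or min(image.shape) < 16:
        raise ValueError("expected a 2-D image with min dimension >= 16")
    h, w = image.shape
    if tile is None or (tile >= h and tile >= w):
        maps = _forward_whole(model, image)
    else:
        if overlap >= tile:
            raise ValueError("overlap must be smaller than tile")
        step = tile - overlap
        acc = np.zeros((N_CLASSES, h, w))
        wsum = np.zeros((h, w))
        win = _tile_window(tile, overlap)
        rows = sorted({min(r, max(h - tile, 0)) for r in range(0, h, step)})
        cols = sorted({min(c, max(w - tile, 0)) for c in range(0, w, step)})
        for r0 in rows:
            for c0 in cols:
                r1, c1 = min(r0 + tile, h), min(c0 + tile, w)
                sub = _forward_whole(model, image[r0:r1, c0:c1])
                wloc = win[: r1 - r0, : c1 - c0]
                acc[:, r0:r1, c0:c1] += sub * wloc
                wsum[r0:r1, c0:c1] += wloc
        maps = acc / wsum
    maps = maps / maps.sum(axis=0, keepdims=True)
    return ProbabilityMaps(maps=maps, source="network")
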