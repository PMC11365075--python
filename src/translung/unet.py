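"""Supervised encoder–decoder baseline segmenter.

A standard U-Net: repeated (conv3x3 → norm → ReLU) × 2 blocks with 2×2 max
pooling on the way down, transposed-convolution upsampling with skip
concatenation on the way up, and a 1×1 projection with a sigmoid head.
Trained with plain pixelwise binary cross-entropy against the mask — no
Dice term, no augmentation — using the same optimiser settings, epoch
semantics and shuffle/seed behaviour as the adversarial translator, so the
two are directly comparable on identical splits and budgets.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    Adam,
    Concat,
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    MaxPool2d,
    ReLU,
    Sigmoid,
)
from .pairs_io import ImagePair, as_gray_image, binarize
from .pix2pix import TrainConfig, _bce, _stack

__all__ = [
    "UNetSpec",
    "TrainedUNet",
    "UNetSegmenter",
    "train_unet",
    "segment_unet",
    "save_unet_checkpoint",
    "load_unet_checkpoint",
]

_CHECKPOINT_VERSION = 1


@dataclass
class UNetSpec:
    input_size: int = 256
    base_channels: int = 64
    depth: int = 4

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_size % (1 << self.depth) != 0:
            raise ValueError(
                f"input_size must be divisible by 2^depth={1 << self.depth}"
            )
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")


class _Block:
    """(conv3x3 → InstanceNorm → ReLU) × 2."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.layers = [
            Conv2d(in_ch, out_ch, 3, 1, 1, rng), InstanceNorm2d(out_ch, rng), ReLU(),
            Conv2d(out_ch, out_ch, 3, 1, 1, rng), InstanceNorm2d(out_ch, rng), ReLU(),
        ]

    def params(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class UNetSegmenter:
    def __init__(self, spec: UNetSpec, seed: int):
        self.spec = spec
        rng = np.random.default_rng(seed)
        b, d = spec.base_channels, spec.depth
        ch = [b * (1 << i) for i in range(d + 1)]
        self.down = [_Block(1 if i == 0 else ch[i - 1], ch[i], rng) for i in range(d)]
        self.pools = [MaxPool2d() for _ in range(d)]
        self.bottom = _Block(ch[d - 1], ch[d], rng)
        self.ups = [ConvTranspose2d(ch[d - i], ch[d - 1 - i], 2, 2, 0, rng) for i in range(d)]
        self.concats = [Concat() for _ in range(d)]
        self.up_blocks = [_Block(2 * ch[d - 1 - i], ch[d - 1 - i], rng) for i in range(d)]
        self.head = Conv2d(ch[0], 1, 1, 1, 0, rng)
        self.sigmoid = Sigmoid()

    def params(self):
        out = []
        for blk in self.down:
            out += blk.params()
        out += self.bottom.params()
        for up, blk in zip(self.ups, self.up_blocks):
            out += up.params() + blk.params()
        out += self.head.params()
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.spec.input_size
        if x.shape[2] != s or x.shape[3] != s:
            raise ValueError(f"segmenter expects {s}x{s} inputs, got {x.shape[2]}x{x.shape[3]}")
        skips = []
        cur = x.astype(np.float32)
        for blk, pool in zip(self.down, self.pools):
            cur = blk.forward(cur)
            skips.append(cur)
            cur = pool.forward(cur)
        cur = self.bottom.forward(cur)
        for up, concat, blk, skip in zip(self.ups, self.concats, self.up_blocks,
                                         reversed(skips)):
            cur = up.forward(cur)
            cur = concat.forward_pair(skip, cur)
            cur = blk.forward(cur)
        return self.sigmoid.forward(self.head.forward(cur))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.head.backward(self.sigmoid.backward(grad))
        skip_grads = []
        for up, concat, blk in zip(reversed(self.ups), reversed(self.concats),
                                   reversed(self.up_blocks)):
            g = blk.backward(g)
            g_skip, g = concat.backward(g)
            skip_grads.append(g_skip)
            g = up.backward(g)
        g = self.bottom.backward(g)
        for blk, pool, g_skip in zip(reversed(self.down), reversed(self.pools),
                                     reversed(skip_grads)):
            g = pool.backward(g)
            g = blk.backward(g + g_skip)
        return g


@dataclass
class TrainedUNet:
    network: UNetSegmenter
    spec: UNetSpec
    config: TrainConfig
    history: list[float] = field(default_factory=list)


def train_unet(pairs: list[ImagePair], spec: UNetSpec, config: TrainConfig) -> TrainedUNet:
    """Minimise mean pixelwise BCE; ``config.lambda_l1`` is ignored."""
    sub = (np.random.SeedSequence(config.seed).generate_state(2) % np.uint32(2**31)).tolist()
    net = UNetSegmenter(spec, seed=int(sub[0]))
    if config.epochs > 0 and not pairs:
        raise ValueError("pairs must be nonempty when epochs > 0")
    shuffle_rng = np.random.default_rng(int(sub[1]))
    opt = Adam(net.params(), lr=config.learning_rate, beta1=config.adam_beta1)

    history: list[float] = []
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(pairs))
        loss_sum, n_steps = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = [pairs[i] for i in order[start : start + config.batch_size]]
            x, y = _stack(batch, spec.input_size)
            prob = net.forward(x)
            loss, grad = _bce_per_pixel(prob, y)
            opt.zero_grad()
            net.backward(grad)
            opt.step()
            loss_sum += loss
            n_steps += 1
        history.append(loss_sum / max(n_steps, 1))
    return TrainedUNet(network=net, spec=spec, config=config, history=history)


def _bce_per_pixel(prob: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    eps = 1e-7
    p = np.clip(prob, eps, 1.0 - eps)
    loss = float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))
    grad = ((p - target) / (p * (1.0 - p)) / p.size).astype(np.float32)
    return loss, grad


def segment_unet(model: TrainedUNet, image: np.ndarray) -> np.ndarray:
    """Forward pass, sigmoid, binarize at 0.5."""
    img = as_gray_image(image)
    prob = model.network.forward(img[None, None])
    return binarize(np.clip(prob[0, 0], 0.0, 1.0), 0.5)


def save_unet_checkpoint(model: TrainedUNet, path: pathlib.Path) -> None:
    meta = {
        "format_version": _CHECKPOINT_VERSION,
        "kind": "unet",
        "spec": asdict(model.spec),
        "config": asdict(model.config),
        "history": model.history,
    }
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.network.params())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_unet_checkpoint(path: pathlib.Path) -> TrainedUNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("kind") != "unet":
            raise ValueError(f"not a U-Net checkpoint: {path}")
        if meta.get("format_version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('format_version')}")
        spec = UNetSpec(**meta["spec"])
        config = TrainConfig(**meta["config"])
        net = UNetSegmenter(spec, seed=0)
        for i, p in enumerate(net.params()):
            stored = data[f"param_{i}"]
            if stored.shape != p.value.shape:
                raise ValueError("checkpoint parameter shapes do not match the spec")
            p.value[...] = stored
    return TrainedUNet(network=net, spec=spec, config=config, history=meta["history"])
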