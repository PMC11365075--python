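"""Conditional adversarial image-to-image translation for segmentation.

The method treats segmentation as style translation: the grayscale input is
the "blurred" image, the binary reference mask (rendered as an image with
foreground 1.0, background 0.0) is the "exact" image, and a conditional GAN
learns the mapping. The combined objective is

    G* = arg min_G max_D  Γ_cGAN(G, D) + λ · Γ_L1(G)

with the conditional adversarial value

    Γ_cGAN(G, D) = E[log D(x, y)] + E[log(1 − D(x, G(x, z)))]

and the reconstruction term Γ_L1(G) = E‖y − G(x, z)‖₁. The noise input z is
realised as dropout in the generator, active during training and optionally
at inference. Inference is translate-then-binarize: the generator output is
thresholded at 0.5 to produce the predicted mask.

Architecture follows the canonical translation-network recipe: a
stride-2 encoder–decoder generator with skip connections (depth
log2(input_size), channels doubling from ``base_channels`` and capped at
8×), and a patch critic that scores local (input, candidate) patches rather
than the whole image. Optimisation is Adam (lr 2e-4, β₁ 0.5), batch size 1,
with the discriminator ascending a halved binary cross-entropy form of
Γ_cGAN and the generator descending the non-saturating adversarial loss
−E[log D(x, G(x))] plus λ·L1 (λ = 100 by default).
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
    Dropout,
    InstanceNorm2d,
    LeakyReLU,
    ReLU,
    Sigmoid,
    Tanh,
)
from .pairs_io import ImagePair, as_gray_image, binarize

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "TrainConfig",
    "LossComponents",
    "TrainedTranslator",
    "UNetGenerator",
    "PatchDiscriminator",
    "build_generator",
    "build_discriminator",
    "cgan_objective",
    "l1_loss",
    "train",
    "translate",
    "segment",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-7  # probability clamp inside logs; keeps Eq. values finite
_CHECKPOINT_VERSION = 1


def _log2_int(n: int) -> int:
    k = int(n).bit_length() - 1
    if n < 32 or (1 << k) != n:
        raise ValueError(f"input_size must be a power of two >= 32, got {n}")
    return k


@dataclass
class GeneratorSpec:
    input_size: int = 256
    base_channels: int = 64
    depth: int | None = None  # defaults to log2(input_size)
    dropout_stages: int = 3
    dropout_rate: float = 0.5
    skip_connections: bool = True

    def __post_init__(self):
        d = _log2_int(self.input_size)
        if self.depth is None:
            self.depth = d
        if self.depth != d:
            raise ValueError(
                f"depth must equal log2(input_size)={d} so the bottleneck is 1x1, got {self.depth}"
            )
        if not 0 <= self.dropout_stages <= self.depth:
            raise ValueError("dropout_stages must lie in [0, depth]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")


@dataclass
class DiscriminatorSpec:
    patch_depth: int = 3  # stride-2 stages; 3 gives the classic 70x70 patch critic
    base_channels: int = 64

    def __post_init__(self):
        if self.patch_depth < 1:
            raise ValueError("patch_depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")


@dataclass
class TrainConfig:
    epochs: int = 20
    lambda_l1: float = 100.0
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    batch_size: int = 1
    seed: int = 0
    device: str = "cpu"
    halve_d_loss: bool = True

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.device not in ("cpu", "accelerator"):
            raise ValueError("device must be 'cpu' or 'accelerator'")


@dataclass(frozen=True)
class LossComponents:
    d_loss: float
    g_adv: float
    g_l1: float
    g_total: float


def _channels(base: int, stage: int) -> int:
    return min(base * (1 << stage), 8 * base)


class UNetGenerator:
    """Stride-2 encoder–decoder translator with skip connections.

    Encoder stage i (i >= 1) is LeakyReLU → Conv(4,2,1) → InstanceNorm; the
    first stage has no activation/norm in front and the innermost stage no
    norm (its spatial extent is 1x1). Decoder stages mirror with
    ReLU → ConvT(4,2,1) → InstanceNorm, dropout in the innermost
    ``dropout_stages`` stages, skip concatenation everywhere but the
    bottleneck, and a final Tanh mapped affinely onto [0, 1].
    """

    def __init__(self, spec: GeneratorSpec, seed: int):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed)
        d = spec.depth
        b = spec.base_channels
        enc_ch = [_channels(b, i) for i in range(d)]

        self.enc: list[tuple] = []
        in_ch = 1
        for i in range(d):
            act = LeakyReLU(0.2) if i > 0 else None
            conv = Conv2d(in_ch, enc_ch[i], 4, 2, 1, rng)
            norm = InstanceNorm2d(enc_ch[i], rng) if 0 < i < d - 1 else None
            self.enc.append((act, conv, norm))
            in_ch = enc_ch[i]

        self.dec: list[tuple] = []
        for j in range(d):
            if j == 0:
                in_ch = enc_ch[d - 1]
            else:
                in_ch = enc_ch[d - 1 - j] * (2 if spec.skip_connections else 1)
            out_ch = enc_ch[d - 2 - j] if j < d - 1 else 1
            act = ReLU()
            convt = ConvTranspose2d(in_ch, out_ch, 4, 2, 1, rng)
            norm = InstanceNorm2d(out_ch, rng) if j < d - 1 else None
            drop = (Dropout(spec.dropout_rate, self._dropout_rng)
                    if j < spec.dropout_stages and j < d - 1 else None)
            concat = Concat() if (j > 0 and spec.skip_connections) else None
            self.dec.append((act, convt, norm, drop, concat))
        self.tanh = Tanh()

    def params(self):
        out = []
        for act, conv, norm in self.enc:
            out += conv.params() + (norm.params() if norm else [])
        for act, convt, norm, drop, concat in self.dec:
            out += convt.params() + (norm.params() if norm else [])
        return out

    def seed_dropout(self, rng: np.random.Generator) -> None:
        self._dropout_rng = rng
        for _, _, _, drop, _ in self.dec:
            if drop is not None:
                drop.set_rng(rng)

    def forward(self, x: np.ndarray, dropout: bool = False) -> np.ndarray:
        if x.shape[2] != self.spec.input_size or x.shape[3] != self.spec.input_size:
            raise ValueError(
                f"generator expects {self.spec.input_size}x{self.spec.input_size} inputs, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        d = self.spec.depth
        skips: list[np.ndarray] = []
        cur = x.astype(np.float32)
        for act, conv, norm in self.enc:
            if act is not None:
                cur = act.forward(cur)
            cur = conv.forward(cur)
            if norm is not None:
                cur = norm.forward(cur)
            skips.append(cur)
        for j, (act, convt, norm, drop, concat) in enumerate(self.dec):
            if concat is not None:
                cur = concat.forward_pair(cur, skips[d - 1 - j])
            cur = act.forward(cur)
            cur = convt.forward(cur)
            if norm is not None:
                cur = norm.forward(cur)
            if drop is not None:
                cur = drop.forward(cur, train=dropout)
        cur = self.tanh.forward(cur)
        return 0.5 * (cur + 1.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        d = self.spec.depth
        g = self.tanh.backward(0.5 * grad_out)
        skip_grads: list[np.ndarray | None] = [None] * d
        for j in reversed(range(d)):
            act, convt, norm, drop, concat = self.dec[j]
            if drop is not None:
                g = drop.backward(g)
            if norm is not None:
                g = norm.backward(g)
            g = convt.backward(g)
            g = act.backward(g)
            if concat is not None:
                g, g_skip = concat.backward(g)
                i = d - 1 - j
                skip_grads[i] = g_skip if skip_grads[i] is None else skip_grads[i] + g_skip
        skip_grads[d - 1] = g if skip_grads[d - 1] is None else skip_grads[d - 1] + g
        gi = None
        for i in reversed(range(d)):
            act, conv, norm = self.enc[i]
            gi = skip_grads[i]
            if norm is not None:
                gi = norm.backward(gi)
            gi = conv.backward(gi)
            if act is not None:
                gi = act.backward(gi)
            if i > 0:
                skip_grads[i - 1] = gi if skip_grads[i - 1] is None else skip_grads[i - 1] + gi
        return gi


class PatchDiscriminator:
    """Patch critic over the channel-concatenated (condition, candidate) pair.

    ``patch_depth`` stride-2 stages with channel doubling (capped at 8×),
    one stride-1 stage, then a stride-1 projection to a single channel and
    a sigmoid: the output is a grid of per-patch real-probabilities.
    """

    def __init__(self, spec: DiscriminatorSpec, seed: int):
        self.spec = spec
        rng = np.random.default_rng(seed)
        b = spec.base_channels
        layers: list = [Conv2d(2, b, 4, 2, 1, rng), LeakyReLU(0.2)]
        in_ch = b
        for i in range(1, spec.patch_depth):
            ch = _channels(b, i)
            layers += [Conv2d(in_ch, ch, 4, 2, 1, rng), InstanceNorm2d(ch, rng), LeakyReLU(0.2)]
            in_ch = ch
        ch = _channels(b, spec.patch_depth)
        layers += [Conv2d(in_ch, ch, 4, 1, 1, rng), InstanceNorm2d(ch, rng), LeakyReLU(0.2)]
        layers += [Conv2d(ch, 1, 4, 1, 1, rng), Sigmoid()]
        self.layers = layers

    def params(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        return out

    def forward(self, condition: np.ndarray, candidate: np.ndarray) -> np.ndarray:
        if condition.shape != candidate.shape:
            raise ValueError(
                f"condition {condition.shape} and candidate {candidate.shape} shapes differ"
            )
        cur = np.concatenate([condition, candidate], axis=1).astype(np.float32)
        for layer in self.layers:
            cur = layer.forward(cur)
        return cur

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns gradients w.r.t. (condition, candidate)."""
        g = grad
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g[:, 0:1], g[:, 1:2]


def build_generator(spec: GeneratorSpec, seed: int) -> UNetGenerator:
    return UNetGenerator(spec, seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int) -> PatchDiscriminator:
    return PatchDiscriminator(spec, seed)


def cgan_objective(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Value of the conditional adversarial objective on critic outputs.

    mean(log D(x,y)) + mean(log(1 − D(x,G(x,z)))); probabilities are clamped
    to [ε, 1−ε] so the value is always finite. Nonpositive; maximised by a
    perfect critic (→ 0).
    """
    pr = np.clip(np.asarray(d_real, dtype=np.float64), _EPS, 1.0 - _EPS)
    pf = np.clip(np.asarray(d_fake, dtype=np.float64), _EPS, 1.0 - _EPS)
    if pr.shape != pf.shape:
        raise ValueError(f"shape mismatch: {pr.shape} vs {pf.shape}")
    return float(np.mean(np.log(pr)) + np.mean(np.log(1.0 - pf)))


def l1_loss(target: np.ndarray, generated: np.ndarray) -> float:
    """Mean absolute per-pixel difference (the reconstruction term)."""
    t = np.asarray(target, dtype=np.float64)
    g = np.asarray(generated, dtype=np.float64)
    if t.shape != g.shape:
        raise ValueError(f"shape mismatch: target {t.shape} vs generated {g.shape}")
    return float(np.mean(np.abs(t - g)))


def _bce(p: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Binary cross-entropy of probabilities toward a constant target,
    with the gradient w.r.t. the probabilities."""
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    loss = float(-np.mean(target * np.log(pc) + (1.0 - target) * np.log(1.0 - pc)))
    grad = ((pc - target) / (pc * (1.0 - pc)) / p.size).astype(np.float32)
    return loss, grad


@dataclass
class TrainedTranslator:
    generator: UNetGenerator
    gspec: GeneratorSpec
    config: TrainConfig
    history: list[LossComponents] = field(default_factory=list)


def _stack(pairs: list[ImagePair], size: int) -> tuple[np.ndarray, np.ndarray]:
    for p in pairs:
        if p.image.shape != (size, size):
            raise ValueError(
                f"pair {p.pair_id!r} is {p.image.shape}, expected {(size, size)}"
            )
    x = np.stack([p.image for p in pairs])[:, None].astype(np.float32)
    y = np.stack([p.mask for p in pairs])[:, None].astype(np.float32)
    return x, y


def train(pairs: list[ImagePair], gspec: GeneratorSpec, dspec: DiscriminatorSpec,
          config: TrainConfig) -> TrainedTranslator:
    """Adversarial training loop.

    Per step: the critic ascends the conditional adversarial objective
    (as BCE toward 1 on real and 0 on translated pairs, averaged and
    halved), then the generator descends the non-saturating adversarial
    loss −mean log D(x, G(x)) plus λ·L1. Dropout is active throughout
    training. Epoch order, initialisation and dropout are all derived from
    ``config.seed``.
    """
    sub = (np.random.SeedSequence(config.seed).generate_state(4) % np.uint32(2**31)).tolist()
    gen = UNetGenerator(gspec, seed=int(sub[0]))
    if config.epochs > 0 and not pairs:
        raise ValueError("pairs must be nonempty when epochs > 0")
    disc = PatchDiscriminator(dspec, seed=int(sub[1]))
    shuffle_rng = np.random.default_rng(int(sub[2]))
    gen.seed_dropout(np.random.default_rng(int(sub[3])))
    g_opt = Adam(gen.params(), lr=config.learning_rate, beta1=config.adam_beta1)
    d_opt = Adam(disc.params(), lr=config.learning_rate, beta1=config.adam_beta1)
    d_scale = 0.5 if config.halve_d_loss else 1.0
    lam = config.lambda_l1

    history: list[LossComponents] = []
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(pairs))
        comp_sums = np.zeros(3)  # d_loss, g_adv, g_l1
        n_steps = 0
        for start in range(0, len(order), config.batch_size):
            batch = [pairs[i] for i in order[start : start + config.batch_size]]
            x, y = _stack(batch, gspec.input_size)
            fake = gen.forward(x, dropout=True)

            # critic step (fake is treated as constant)
            d_opt.zero_grad()
            p_real = disc.forward(x, y)
            loss_real, g_real = _bce(p_real, 1.0)
            disc.backward(g_real * d_scale)
            p_fake = disc.forward(x, fake)
            loss_fake, g_fake = _bce(p_fake, 0.0)
            disc.backward(g_fake * d_scale)
            d_opt.step()
            d_loss = d_scale * (loss_real + loss_fake)

            # generator step (critic frozen; its gradients are discarded)
            g_opt.zero_grad()
            p_fake2 = disc.forward(x, fake)
            g_adv, g_prob = _bce(p_fake2, 1.0)
            _, d_candidate = disc.backward(g_prob)
            g_l1 = l1_loss(y, fake)
            d_l1 = np.sign(fake - y, dtype=np.float32) / fake.size
            gen.backward(d_candidate + lam * d_l1)
            g_opt.step()

            comp_sums += (d_loss, g_adv, g_l1)
            n_steps += 1
        d_mean, adv_mean, l1_mean = comp_sums / max(n_steps, 1)
        history.append(LossComponents(d_loss=d_mean, g_adv=adv_mean, g_l1=l1_mean,
                                      g_total=adv_mean + lam * l1_mean))
    return TrainedTranslator(generator=gen, gspec=gspec, config=config, history=history)


def translate(model: TrainedTranslator, image: np.ndarray, stochastic: bool = False,
              seed: int = 0) -> np.ndarray:
    """Generator forward pass. ``stochastic=True`` keeps dropout active
    (the translator's noise input), seeded for reproducibility."""
    img = as_gray_image(image)
    if stochastic:
        model.generator.seed_dropout(np.random.default_rng(seed))
    out = model.generator.forward(img[None, None], dropout=stochastic)
    return np.clip(out[0, 0], 0.0, 1.0).astype(np.float32)


def segment(model: TrainedTranslator, image: np.ndarray) -> np.ndarray:
    """Deterministic translate-then-binarize inference at threshold 0.5."""
    return binarize(translate(model, image, stochastic=False), 0.5)


def save_checkpoint(model: TrainedTranslator, path: pathlib.Path) -> None:
    """Single-archive checkpoint: specs, config, history and parameter tensors."""
    meta = {
        "format_version": _CHECKPOINT_VERSION,
        "kind": "pix2pix",
        "gspec": asdict(model.gspec),
        "config": asdict(model.config),
        "history": [asdict(h) for h in model.history],
    }
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.generator.params())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: pathlib.Path) -> TrainedTranslator:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("kind") != "pix2pix":
            raise ValueError(f"not a translator checkpoint: {path}")
        if meta.get("format_version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('format_version')}")
        gspec = GeneratorSpec(**meta["gspec"])
        config = TrainConfig(**meta["config"])
        gen = UNetGenerator(gspec, seed=0)
        params = gen.params()
        for i, p in enumerate(params):
            stored = data[f"param_{i}"]
            if stored.shape != p.value.shape:
                raise ValueError("checkpoint parameter shapes do not match the spec")
            p.value[...] = stored
    history = [LossComponents(**h) for h in meta["history"]]
    return TrainedTranslator(generator=gen, gspec=gspec, config=config, history=history)
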