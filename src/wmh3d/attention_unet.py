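"""Attention U-Net for white-matter-hyperintensity segmentation.

A 4-level U-shaped encoder/decoder.  Each stage is a double 3x3
convolution block, optionally with an identity (residual) shortcut, and
optionally followed by a CBAM attention block — a per-channel gate computed
from globally pooled descriptors through a shared two-layer MLP, then a
per-pixel spatial gate from a 7x7 convolution over the channel-pooled
maps.  Encoder stages are joined by 2x2 max-pooling; decoder stages
upsample with 2x2 transposed convolutions and concatenate the matching
encoder skip.  The head is a 1x1 convolution with a sigmoid, producing a
lesion-probability map the size of the input.

Toggling ``use_residual`` / ``use_cbam`` yields the ablation line
plain U-Net -> ResU-Net -> Attention U-Net.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported convenience for training code)
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Linear,
    Module,
    Tensor,
    concat,
    maxpool2d,
    reduce_max,
    reduce_mean,
    reduce_sum,
    relu,
    sigmoid,
)

__all__ = [
    "ModelConfig",
    "AttentionWeights",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "ConvBlock",
    "AttentionUnet",
    "build_network",
    "channel_attention",
    "spatial_attention",
    "cbam_block",
    "residual_block",
    "dice_loss",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture description.

    ``base_channels`` is the width of the first encoder stage; widths
    double at every level (64 -> 128 -> 256 -> 512 with a 1024-channel
    bottleneck at the defaults).  ``reduction_ratio`` is the channel
    bottleneck r of the attention MLP; every stage width where CBAM is
    applied must be divisible by it.
    """

    depth: int = 4
    base_channels: int = 64
    reduction_ratio: int = 16
    use_residual: bool = True
    use_cbam: bool = True
    in_channels: int = 1
    out_channels: int = 1
    conv_kernel: int = 3
    pool_kernel: int = 2
    upsample_kernel: int = 2
    spatial_attention_kernel: int = 7

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.use_cbam and self.base_channels % self.reduction_ratio != 0:
            raise ValueError(
                f"base_channels={self.base_channels} must be divisible by "
                f"reduction_ratio={self.reduction_ratio} where CBAM is applied"
            )

    def stage_channels(self) -> list[int]:
        """Widths of the encoder stages plus the bottleneck."""
        return [self.base_channels * 2**i for i in range(self.depth + 1)]


@dataclass
class AttentionWeights:
    """Raw CBAM weights, for evaluating the attention maps functionally.

    ``w0`` (C/r, C) and ``w1`` (C, C/r) are the shared-MLP weights used by
    both the average-pool and max-pool branches; ``spatial_kernel`` is the
    (1, 2, 7, 7) convolution applied to the stacked channel-mean and
    channel-max maps.
    """

    w0: np.ndarray
    w1: np.ndarray
    spatial_kernel: np.ndarray
    spatial_bias: np.ndarray


class ChannelAttention(Module):
    """Per-channel gate sigma(MLP(AvgPool(F)) + MLP(MaxPool(F)))."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels % reduction != 0:
            raise ValueError(
                f"channels={channels} not divisible by reduction ratio {reduction}"
            )
        hidden = channels // reduction
        self.fc0 = Linear(channels, hidden, rng, bias=False)
        self.fc1 = Linear(hidden, channels, rng, bias=False)
        # neutral start: a zero second layer makes the gate exactly 0.5
        # everywhere, so attention perturbs nothing until it has learned
        # something (gradients reach fc1 immediately, then fc0)
        self.fc1.weight.data[:] = 0.0

    def gate(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = reduce_mean(x, axis=(2, 3))          # (N, C)
        mx = reduce_max(x, axis=(2, 3))            # (N, C)
        g = sigmoid(self.fc1(relu(self.fc0(avg))) + self.fc1(relu(self.fc0(mx))))
        return g.reshape(n, c, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        return self.gate(x) * x


class SpatialAttention(Module):
    """Per-pixel gate sigma(conv7x7([channel-mean; channel-max]))."""

    def __init__(self, rng: np.random.Generator, kernel: int = 7):
        self.conv = Conv2d(2, 1, kernel, padding=kernel // 2, rng=rng)
        # neutral start (uniform 0.5 gate), as for the channel branch
        self.conv.weight.data[:] = 0.0

    def gate(self, x: Tensor) -> Tensor:
        avg = reduce_mean(x, axis=1, keepdims=True)   # (N, 1, H, W)
        mx = reduce_max(x, axis=1, keepdims=True)
        return sigmoid(self.conv(concat([avg, mx], axis=1)))

    def forward(self, x: Tensor) -> Tensor:
        return self.gate(x) * x


class CBAM(Module):
    """Channel gate followed by spatial gate, each multiplied onto F."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 spatial_kernel: int = 7):
        self.channel = ChannelAttention(channels, reduction, rng)
        self.spatial = SpatialAttention(rng, kernel=spatial_kernel)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(self.channel(x))

    def weights(self) -> AttentionWeights:
        return AttentionWeights(
            w0=self.channel.fc0.weight.data,
            w1=self.channel.fc1.weight.data,
            spatial_kernel=self.spatial.conv.weight.data,
            spatial_bias=self.spatial.conv.bias.data,
        )


class ConvBlock(Module):
    """Double 3x3 convolution stage, optionally residual.

    Each convolution is batch-normalized (conv - BN - ReLU), the standard
    recipe for this network family; without normalization a 4-level
    encoder/decoder saturates its output sigmoid at initialization and the
    Dice loss cannot recover.  Residual form:
    relu(BN(conv(relu(BN(conv(x))))) + shortcut(x)) with an identity
    shortcut, or a 1x1 projection (+BN) when the channel count changes.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 residual: bool = True, kernel: int = 3):
        pad = kernel // 2
        self.conv1 = Conv2d(cin, cout, kernel, padding=pad, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, kernel, padding=pad, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.residual = residual
        self.shortcut = None
        self.shortcut_bn = None
        if residual and cin != cout:
            self.shortcut = Conv2d(cin, cout, 1, padding=0, rng=rng, bias=False)
            self.shortcut_bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn2(self.conv2(relu(self.bn1(self.conv1(x)))))
        if self.residual:
            if self.shortcut is not None:
                s = self.shortcut_bn(self.shortcut(x))
            else:
                s = x
            return relu(h + s)
        return relu(h)


class AttentionUnet(Module):
    """The full U-shaped network; see the module docstring."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        # separate streams for the convolutional trunk and the attention
        # blocks: ablation variants at the same seed then share identical
        # trunk initializations (paired comparisons)
        trunk_ss, attn_ss = np.random.SeedSequence(seed).spawn(2)
        rng = np.random.default_rng(trunk_ss)
        rng_attn = np.random.default_rng(attn_ss)
        chans = config.stage_channels()
        d = config.depth

        self.encoders: list[Module] = []
        self.encoder_cbam: list[Module | None] = []
        cin = config.in_channels
        for i in range(d):
            self.encoders.append(
                ConvBlock(cin, chans[i], rng, residual=config.use_residual,
                          kernel=config.conv_kernel)
            )
            self.encoder_cbam.append(
                CBAM(chans[i], config.reduction_ratio, rng_attn,
                     config.spatial_attention_kernel)
                if config.use_cbam else None
            )
            cin = chans[i]
        self.n_pool_stages = d

        self.bottleneck = ConvBlock(chans[d - 1], chans[d], rng,
                                    residual=config.use_residual,
                                    kernel=config.conv_kernel)

        self.upsamples: list[Module] = []
        self.decoders: list[Module] = []
        self.decoder_cbam: list[Module | None] = []
        for i in reversed(range(d)):
            self.upsamples.append(ConvTranspose2d(chans[i + 1], chans[i], rng))
            self.decoders.append(
                ConvBlock(2 * chans[i], chans[i], rng,
                          residual=config.use_residual,
                          kernel=config.conv_kernel)
            )
            self.decoder_cbam.append(
                CBAM(chans[i], config.reduction_ratio, rng_attn,
                     config.spatial_attention_kernel)
                if config.use_cbam else None
            )
        self.n_upsample_stages = d

        self.head = Conv2d(chans[0], config.out_channels, 1, padding=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        d = self.config.depth
        h, w = x.shape[2], x.shape[3]
        for name, dim in (("height", h), ("width", w)):
            if dim % 2**d != 0:
                raise ValueError(
                    f"input {name} {dim} is not divisible by 2^depth = {2**d}"
                )
        skips = []
        for enc, cb in zip(self.encoders, self.encoder_cbam):
            x = enc(x)
            if cb is not None:
                x = cb(x)
            skips.append(x)
            x = maxpool2d(x, self.config.pool_kernel)
        x = self.bottleneck(x)
        for up, dec, cb, skip in zip(
            self.upsamples, self.decoders, self.decoder_cbam, reversed(skips)
        ):
            x = up(x)
            x = dec(concat([skip, x], axis=1))
            if cb is not None:
                x = cb(x)
        return sigmoid(self.head(x))

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Inference pass on a (N, H, W) or (N, 1, H, W) array -> (N, H, W).

        Runs in eval mode (batch-norm running statistics), so the result
        does not depend on how the slices are batched.
        """
        arr = np.asarray(images, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[:, None]
        self.set_training(False)
        try:
            return self.forward(Tensor(arr)).data[:, 0]
        finally:
            self.set_training(True)


def build_network(config: ModelConfig, seed: int = 0) -> AttentionUnet:
    """Construct a network with reproducible (seeded) initialization."""
    return AttentionUnet(config, seed=seed)


# ---------------------------------------------------------------------------
# Functional attention ops (numpy in, numpy out) — evaluate the gates for a
# given feature map and explicit weights.
# ---------------------------------------------------------------------------

def _module_from_weights(weights: AttentionWeights) -> CBAM:
    c = weights.w0.shape[1]
    r = c // weights.w0.shape[0]
    cb = CBAM(c, r, np.random.default_rng(0),
              spatial_kernel=weights.spatial_kernel.shape[-1])
    cb.channel.fc0.weight.data = np.asarray(weights.w0, dtype=np.float64)
    cb.channel.fc1.weight.data = np.asarray(weights.w1, dtype=np.float64)
    cb.spatial.conv.weight.data = np.asarray(weights.spatial_kernel, dtype=np.float64)
    cb.spatial.conv.bias.data = np.asarray(weights.spatial_bias, dtype=np.float64)
    return cb


def channel_attention(F: np.ndarray, weights: AttentionWeights) -> np.ndarray:
    """Per-channel gate in (0,1)^C for a (N, C, H, W) feature map."""
    cb = _module_from_weights(weights)
    return cb.channel.gate(Tensor(F)).data[:, :, 0, 0]


def spatial_attention(F: np.ndarray, weights: AttentionWeights) -> np.ndarray:
    """Per-pixel gate in (0,1)^(H x W) for a (N, C, H, W) feature map."""
    cb = _module_from_weights(weights)
    return cb.spatial.gate(Tensor(F)).data[:, 0]


def cbam_block(F: np.ndarray, weights: AttentionWeights) -> np.ndarray:
    """Channel-then-spatial gated feature map, same shape as ``F``."""
    cb = _module_from_weights(weights)
    return cb(Tensor(F)).data


def residual_block(F: np.ndarray, block: ConvBlock) -> np.ndarray:
    """Apply a (residual) convolution stage to a (N, C, H, W) array."""
    return block(Tensor(F)).data


# ---------------------------------------------------------------------------
# Dice loss
# ---------------------------------------------------------------------------

def dice_loss(prediction, target, eps: float = 1.0):
    """Soft Dice loss  1 - (2 sum(p t) + eps) / (sum(p) + sum(t) + eps).

    ``prediction`` holds probabilities in [0, 1]; ``target`` is binary.
    With ``eps`` in numerator and denominator the loss is 0 when both masks
    are empty, and stays finite on empty batches.  Accepts numpy arrays
    (returns a float) or an autodiff :class:`Tensor` prediction (returns a
    Tensor so the loss can be backpropagated).
    """
    if isinstance(prediction, Tensor):
        t = Tensor(np.asarray(target, dtype=np.float64))
        if prediction.shape != t.shape:
            raise ValueError(
                f"shape mismatch: prediction {prediction.shape} vs target {t.shape}"
            )
        inter = reduce_sum(prediction * t)
        denom = reduce_sum(prediction) + reduce_sum(t)
        return 1.0 - (2.0 * inter + eps) / (denom + eps)
    p = np.asarray(prediction, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs target {t.shape}")
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(network: AttentionUnet, path: str | Path) -> None:
    """Save parameters with the ModelConfig embedded."""
    arrays = {f"param_{i}": a for i, a in enumerate(network.state_arrays())}
    np.savez(str(path), config=json.dumps(asdict(network.config)), **arrays)


def load_checkpoint(path: str | Path) -> AttentionUnet:
    with np.load(str(path), allow_pickle=False) as data:
        config = ModelConfig(**json.loads(str(data["config"])))
        n = sum(1 for k in data.files if k.startswith("param_"))
        arrays = [data[f"param_{i}"] for i in range(n)]
    net = AttentionUnet(config)
    net.load_state_arrays(arrays)
    return net
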