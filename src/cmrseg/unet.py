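"""Modified 2D U-Net for four-class short-axis segmentation.

Five encoder levels of [conv3x3-BN-ReLU x2] with 2x2 max pooling between
them, a decoder of four stages of [2x bilinear upsample -> concatenate skip
-> dropout -> conv3x3-BN-ReLU x2], and a 1x1 convolution head to four logits.
Relative to the classic U-Net, batch normalization follows every hidden
convolution and dropout follows every concatenation; upsampling is
parameter-free, the bottleneck width is capped at 8f, and the decoder widths
are (4f, 2f, f, f), which makes the width parameter f the single capacity
dial: f=64 gives ~13.4 million convolution weights, f=16 gives ~0.84 million
(a 16x ratio, i.e. each layer's filter count scaled by 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .types import ValidationError


@dataclass
class UNetConfig:
    """Width/regularization settings; f=64 and f=16 are the two named models."""

    base_filters: int = 64
    in_channels: int = 1
    out_classes: int = 4
    dropout_rate: float = 0.2
    levels: int = 5

    def __post_init__(self) -> None:
        if self.base_filters < 1:
            raise ValidationError("base_filters must be >= 1")
        if self.out_classes != 4:
            raise ValidationError("this network segments exactly 4 classes")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")

    @property
    def encoder_channels(self) -> Tuple[int, ...]:
        f = self.base_filters
        return (f, 2 * f, 4 * f, 8 * f, 8 * f)

    @property
    def decoder_channels(self) -> Tuple[int, ...]:
        f = self.base_filters
        return (4 * f, 2 * f, f, f)


@dataclass
class NetworkDescription:
    """Ordered layer list with per-layer convolution weight counts."""

    layers: List[Tuple[str, int, int, int]] = field(default_factory=list)
    # entries: (kind, c_in, c_out, kernel); non-conv layers use c_in=c_out, kernel=0

    def add(self, kind: str, c_in: int = 0, c_out: int = 0, kernel: int = 0) -> None:
        self.layers.append((kind, c_in, c_out, kernel))

    def conv_layers(self):
        return [l for l in self.layers if l[0] == "conv"]

    def to_table(self) -> str:
        rows = [f"{'#':>3} {'layer':<12} {'c_in':>6} {'c_out':>6} {'k':>3} {'weights':>12}"]
        for i, (kind, ci, co, k) in enumerate(self.layers):
            w = k * k * ci * co if kind == "conv" else 0
            rows.append(f"{i:>3} {kind:<12} {ci:>6} {co:>6} {k:>3} {w:>12,}")
        rows.append(f"{'':>3} {'TOTAL conv':<12} {'':>6} {'':>6} {'':>3} "
                    f"{count_conv_weights(self):>12,}")
        return "\n".join(rows)


def count_conv_weights(description: NetworkDescription) -> int:
    """Sum of k_h * k_w * c_in * c_out over convolutional layers only
    (biases and batch-norm parameters excluded)."""
    return sum(k * k * ci * co for kind, ci, co, k in description.layers
               if kind == "conv")


def describe_unet(config: UNetConfig) -> NetworkDescription:
    """Build the layer description without allocating any weights."""
    d = NetworkDescription()
    enc = config.encoder_channels
    dec = config.decoder_channels
    c = config.in_channels
    for level, ch in enumerate(enc):
        for _ in range(2):
            d.add("conv", c, ch, 3)
            d.add("batchnorm", ch, ch)
            d.add("relu", ch, ch)
            c = ch
        if level < len(enc) - 1:
            d.add("maxpool", c, c)
    skips = list(enc[:-1])[::-1]
    for ch, skip in zip(dec, skips):
        d.add("upsample", c, c)
        d.add("concat", c + skip, c + skip)
        d.add("dropout", c + skip, c + skip)
        c = c + skip
        for _ in range(2):
            d.add("conv", c, ch, 3)
            d.add("batchnorm", ch, ch)
            d.add("relu", ch, ch)
            c = ch
    d.add("conv", c, config.out_classes, 1)
    return d


class _ConvBlock:
    """[conv3x3 - BN - ReLU] x2."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        self.layers: List[nn.Layer] = []
        c = c_in
        for _ in range(2):
            self.layers += [nn.Conv2d(c, c_out, 3, bias=False, rng=rng),
                            nn.BatchNorm2d(c_out), nn.ReLU()]
            c = c_out

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, d):
        for l in reversed(self.layers):
            d = l.backward(d)
        return d


class UNet:
    """The trainable network; built from :class:`UNetConfig`.

    Accepts input batches of shape (N, 1, H, W) with H and W divisible by
    2^(levels-1) = 16, and returns logits of shape (N, 4, H, W).
    """

    def __init__(self, config: UNetConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        self.rng = rng
        enc = config.encoder_channels
        dec = config.decoder_channels
        self.enc_blocks: List[_ConvBlock] = []
        c = config.in_channels
        for ch in enc:
            self.enc_blocks.append(_ConvBlock(c, ch, rng))
            c = ch
        self.pools = [nn.MaxPool2x2() for _ in range(len(enc) - 1)]
        skips = list(enc[:-1])[::-1]
        self.ups: List[nn.BilinearUp2x] = []
        self.dropouts: List[nn.Dropout] = []
        self.dec_blocks: List[_ConvBlock] = []
        for ch, skip in zip(dec, skips):
            self.ups.append(nn.BilinearUp2x())
            self.dropouts.append(nn.Dropout(config.dropout_rate, rng))
            self.dec_blocks.append(_ConvBlock(c + skip, ch, rng))
            c = ch
        self.head = nn.Conv2d(c, config.out_classes, 1, bias=True, rng=rng)
        self.description = describe_unet(config)

    # ---- plumbing -------------------------------------------------------
    def _all_layers(self) -> List[nn.Layer]:
        layers: List[nn.Layer] = []
        for b in self.enc_blocks:
            layers += b.layers
        for b in self.dec_blocks:
            layers += b.layers
        layers.append(self.head)
        return layers

    def num_conv_weights(self) -> int:
        return count_conv_weights(self.description)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        """Point every dropout layer at one shared stream (for seeding runs)."""
        self.rng = rng
        for drop in self.dropouts:
            drop.rng = rng

    def state_dict(self) -> Dict[str, np.ndarray]:
        state: Dict[str, np.ndarray] = {}
        for i, l in enumerate(self._all_layers()):
            for k, v in l.params.items():
                state[f"layer{i}.{k}"] = v.copy()
            if isinstance(l, nn.BatchNorm2d):
                state[f"layer{i}.running_mean"] = l.running_mean.copy()
                state[f"layer{i}.running_var"] = l.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self._all_layers()):
            for k in l.params:
                l.params[k][...] = state[f"layer{i}.{k}"]
            if isinstance(l, nn.BatchNorm2d):
                l.running_mean[...] = state[f"layer{i}.running_mean"]
                l.running_var[...] = state[f"layer{i}.running_var"]

    # ---- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, np.newaxis]
        n, c, h, w = x.shape
        div = 2 ** (self.config.levels - 1)
        if h % div or w % div:
            raise ValidationError(
                f"input spatial size {(h, w)} must be divisible by {div}")
        skips = []
        for i, block in enumerate(self.enc_blocks):
            x = block.forward(x, train)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, drop, block, skip in zip(self.ups, self.dropouts,
                                         self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([x, skip], axis=1)
            x = drop.forward(x, train)
            x = block.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        # decoder stage j consumed skips[L-1-j]; processing stages in reverse
        # order (j = L-1 .. 0) therefore yields skip gradients in encoder
        # order, so dskips[i] aligns with skips[i].
        dskips = []
        for up, drop, block in zip(reversed(self.ups), reversed(self.dropouts),
                                   reversed(self.dec_blocks)):
            d = block.backward(d)
            d = drop.backward(d)
            c_up = d.shape[1] - self._skip_channels[len(dskips)]
            dskips.append(np.ascontiguousarray(d[:, c_up:]))
            d = up.backward(np.ascontiguousarray(d[:, :c_up]))
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            if i < len(self.pools):
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            d = self.enc_blocks[i].backward(d)

    def predict_scores(self, slices: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Eval-mode class probabilities for a (Z, H, W) stack -> (Z, 4, H, W)."""
        outs = []
        for i in range(0, slices.shape[0], batch_size):
            logits = self.forward(slices[i:i + batch_size], train=False)
            outs.append(nn.softmax(logits))
        return np.concatenate(outs, axis=0)


def build_unet(config: UNetConfig, seed: int = 0) -> Tuple[UNet, NetworkDescription]:
    """Instantiate the network and return it with its layer description."""
    net = UNet(config, seed=seed)
    return net, net.description
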