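"""Skip-connected encoder-decoder (U-Net) with a softmax head.

The decoder upsamples with nearest-neighbor interpolation followed by a
convolution, which avoids the checkerboard artifacts of transposed
convolutions.  A network of encoder depth ``d`` contains ``4*d + 3``
convolutional layers (two per encoder level, two in the bottleneck, two per
decoder level, one 1x1 head), so depth 3 gives the classic 15-layer layout.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    MaxPool2d,
    Module,
    ReLU,
    SeparableConv2d,
    Sequential,
    Softmax,
    UpsampleNearest2d,
)


def _conv_block(in_ch, out_ch, rng, conv_style, batch_norm, dtype):
    conv = SeparableConv2d if conv_style == "separable" else Conv2d
    layers = [conv(in_ch, out_ch, rng, dtype=dtype)]
    if batch_norm:
        layers.append(BatchNorm2d(out_ch, dtype=dtype))
    layers.append(ReLU())
    layers.append(conv(out_ch, out_ch, rng, dtype=dtype))
    if batch_norm:
        layers.append(BatchNorm2d(out_ch, dtype=dtype))
    layers.append(ReLU())
    return Sequential(*layers)


class UNet(Module):
    def __init__(
        self,
        in_ch: int,
        n_classes: int,
        base_width: int = 8,
        depth: int = 2,
        conv_style: str = "standard",
        batch_norm: bool = True,
        seed: int = 0,
        dtype=np.float32,
    ):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if base_width < 2:
            raise ValueError("base_width must be >= 2")
        if conv_style not in ("standard", "separable"):
            raise ValueError(f"unknown conv_style {conv_style!r}")
        rng = np.random.default_rng(seed)
        self.in_ch, self.n_classes, self.depth = in_ch, n_classes, depth
        self.base_width, self.conv_style = base_width, conv_style
        self.batch_norm, self.seed, self.dtype = batch_norm, seed, dtype

        widths = [base_width * 2**i for i in range(depth)]
        self.enc = []
        ch = in_ch
        for w in widths:
            self.enc.append(_conv_block(ch, w, rng, conv_style, batch_norm, dtype))
            ch = w
        self.pools = [MaxPool2d() for _ in range(depth)]
        bott_w = base_width * 2**depth
        self.bottleneck = _conv_block(ch, bott_w, rng, conv_style, batch_norm, dtype)
        self.ups = [UpsampleNearest2d() for _ in range(depth)]
        self.dec = []
        ch = bott_w
        for w in reversed(widths):
            self.dec.append(_conv_block(ch + w, w, rng, conv_style, batch_norm, dtype))
            ch = w
        self.head = Conv2d(ch, n_classes, rng, k=1, dtype=dtype)
        self.softmax = Softmax()

    # ----- parameter plumbing -------------------------------------------

    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for blk in self.dec:
            out += blk.params()
        out += self.head.params()
        return out

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All state needed to restore the network: params + BN statistics."""
        out = {}
        for i, p in enumerate(self.params()):
            out[f"param_{i}"] = p.data
        for i, bn in enumerate(self._batchnorms()):
            out[f"bn_{i}_mean"] = bn.running_mean
            out[f"bn_{i}_var"] = bn.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.data = state[f"param_{i}"].astype(self.dtype).reshape(p.data.shape)
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = state[f"bn_{i}_mean"].astype(self.dtype).copy()
            bn.running_var = state[f"bn_{i}_var"].astype(self.dtype).copy()

    def _batchnorms(self):
        bns = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            bns += [m for m in blk.modules if isinstance(m, BatchNorm2d)]
        return bns

    # ----- forward / backward -------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        f = 2**self.depth
        if h % f or w % f:
            raise ValueError(
                f"input spatial size {h}x{w} not divisible by 2^depth={f}"
            )
        x = x.astype(self.dtype, copy=False)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_widths = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_widths.append((x.shape[1], skip.shape[1]))
            x = np.concatenate([x, skip], axis=1)
            x = blk.forward(x, train)
        x = self.head.forward(x, train)
        return self.softmax.forward(x, train)

    def backward(self, dprobs: np.ndarray) -> np.ndarray:
        d = self.softmax.backward(dprobs)
        d = self.head.backward(d)
        dskips = []
        for up, blk, (wu, ws) in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_widths)
        ):
            d = blk.backward(d)
            dskips.append(d[:, wu:])
            d = up.backward(d[:, :wu])
        d = self.bottleneck.backward(d)
        # dskips[0] pairs with the shallowest skip; walk encoder deepest-first
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = d + dskip
            d = blk.backward(d)
        return d

    def predict_probs(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Evaluation-mode forward pass over a batch, in chunks."""
        outs = [
            self.forward(x[i : i + batch_size], train=False)
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)
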