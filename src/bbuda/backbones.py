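"""Configurable encoder-decoder segmentation backbones.

Two convolution styles are available: ``standard`` (plain 3x3 convolutions)
and ``separable`` (depthwise + pointwise, MobileNet-style), the latter with
markedly fewer parameters at equal width/depth.  The softmax lives inside
the network, so every forward pass returns valid per-pixel class
distributions; losses consume probabilities directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .engine import UNet


@dataclass
class BackboneConfig:
    n_channels_in: int = 4
    n_classes: int = 4
    base_width: int = 8
    depth: int = 2
    conv_style: str = "standard"
    batch_norm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_width < 2:
            raise ValueError("base_width must be >= 2")
        if self.conv_style not in ("standard", "separable"):
            raise ValueError("conv_style must be 'standard' or 'separable'")


def full_scale_config(n_channels_in: int = 4, n_classes: int = 4) -> BackboneConfig:
    """Full-scale preset: 15 convolutional layers (depth 3) for 128x128 inputs.

    The encoder/decoder split of a "15-layer" U-Net is not uniquely
    determined; this preset uses 3 encoder levels x 2 convs, a 2-conv
    bottleneck, 3 decoder levels x 2 convs and a 1x1 head.
    """
    return BackboneConfig(
        n_channels_in=n_channels_in, n_classes=n_classes, base_width=16, depth=3
    )


def build_network(config: BackboneConfig) -> UNet:
    """Build a seeded, softmax-headed segmentation network."""
    return UNet(
        in_ch=config.n_channels_in,
        n_classes=config.n_classes,
        base_width=config.base_width,
        depth=config.depth,
        conv_style=config.conv_style,
        batch_norm=config.batch_norm,
        seed=config.seed,
    )


def predict_probs(net: UNet, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Evaluation-mode per-pixel class probabilities, shape (N, C, H, W)."""
    if images.ndim == 3:
        images = images[None]
    if images.shape[1] != net.in_ch:
        raise ValueError(
            f"batch has {images.shape[1]} channels, network expects {net.in_ch}"
        )
    return net.predict_probs(images, batch_size=batch_size)


def count_parameters(net: UNet) -> int:
    return net.parameter_count()


def save_checkpoint(net: UNet, config: BackboneConfig, path: str | Path,
                    extra: dict | None = None) -> None:
    """Weights as .npz plus a JSON sidecar holding the config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **net.state_arrays())
    sidecar = {"config": asdict(config)}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[UNet, BackboneConfig]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = BackboneConfig(**sidecar["config"])
    net = build_network(config)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as st:
        net.load_state_arrays(dict(st))
    return net, config
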