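"""The black-box contract around the fixed source model.

During adaptation the source network may be used only as an opaque
image -> probabilities API: its parameters, architecture and gradients are
off limits.  :func:`seal` wraps a trained network in a handle that enforces
this — the network object is captured in a closure rather than stored as an
attribute, and the conventional access points (``parameters``,
``state_dict``, ...) raise :class:`BlackBoxViolationError`.

Because predictions are plain detached arrays, no gradient can flow back
into the sealed model by construction; an integration test additionally
verifies that source parameters are bit-identical after a full adaptation
run.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np


class BlackBoxViolationError(RuntimeError):
    """Raised on any attempt to look inside a sealed source model."""


_FORBIDDEN = (
    "parameters", "params", "state_dict", "state_arrays", "weights",
    "net", "network", "model", "backward", "load_state_arrays",
)


class BlackBoxPredictor:
    """Opaque image -> ProbabilityMaps handle with a query counter."""

    def __init__(self, predict_fn, n_channels_in: int, n_classes: int,
                 hard_labels: bool = False):
        self._predict_fn = predict_fn
        self.n_channels_in = n_channels_in
        self.n_classes = n_classes
        self.hard_labels = hard_labels
        self.call_count = 0

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel softmax histograms for a batch, shape (N, C, H, W)."""
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        if images.shape[1] != self.n_channels_in:
            raise ValueError(
                f"batch has {images.shape[1]} channels, black box expects "
                f"{self.n_channels_in}"
            )
        self.call_count += 1
        probs = self._predict_fn(images)
        if self.hard_labels:
            hard = probs.argmax(axis=1)
            probs = np.eye(self.n_classes, dtype=probs.dtype)[hard]
            probs = probs.transpose(0, 3, 1, 2)
        return probs

    def __call__(self, images: np.ndarray) -> np.ndarray:
        return self.predict(images)

    def __getattr__(self, name):
        # only reached for attributes not found normally
        if name in _FORBIDDEN:
            raise BlackBoxViolationError(
                f"access to {name!r} violates the black-box contract: the "
                "source model is reachable only as image -> prediction"
            )
        raise AttributeError(name)


def seal(net, trained: bool = True, hard_labels: bool = False) -> BlackBoxPredictor:
    """Wrap a segmentation network into a black-box prediction API.

    The returned handle holds the network only inside a closure; predictions
    are computed in evaluation mode and returned as detached arrays.
    """
    if not trained:
        warnings.warn(
            "sealing a network flagged as untrained; its predictions will be "
            "near-uniform", stacklevel=2,
        )

    def _predict(images: np.ndarray) -> np.ndarray:
        return np.array(net.predict_probs(images), copy=True)

    return BlackBoxPredictor(_predict, net.in_ch, net.n_classes,
                             hard_labels=hard_labels)


def seal_from_directory(dump_dir: str | Path) -> BlackBoxPredictor:
    """Serve predictions from an offline per-image dump (``remote`` mode).

    The directory holds ``index.json`` mapping image content hashes to
    ``.npz`` files with a ``probs`` array, emulating an API whose answers
    were exported ahead of time.
    """
    dump = Path(dump_dir)
    index = json.loads((dump / "index.json").read_text())
    meta = index["meta"]

    def _predict(images: np.ndarray) -> np.ndarray:
        outs = []
        for img in images:
            key = _image_key(img)
            if key not in index["images"]:
                raise KeyError("image not present in the offline prediction dump")
            with np.load(dump / index["images"][key]) as f:
                outs.append(f["probs"])
        return np.stack(outs)

    return BlackBoxPredictor(_predict, meta["n_channels_in"], meta["n_classes"])


def dump_predictions(bb: BlackBoxPredictor, images: np.ndarray,
                     dump_dir: str | Path) -> None:
    """Export a black box's answers for :func:`seal_from_directory`."""
    dump = Path(dump_dir)
    dump.mkdir(parents=True, exist_ok=True)
    index = {
        "meta": {"n_channels_in": bb.n_channels_in, "n_classes": bb.n_classes},
        "images": {},
    }
    for i, img in enumerate(images):
        probs = bb.predict(img[None])[0]
        fname = f"pred_{i:05d}.npz"
        np.savez_compressed(dump / fname, probs=probs)
        index["images"][_image_key(img)] = fname
    (dump / "index.json").write_text(json.dumps(index))


def _image_key(img: np.ndarray) -> str:
    import hashlib

    return hashlib.sha256(np.ascontiguousarray(img, dtype=np.float32).tobytes()).hexdigest()
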