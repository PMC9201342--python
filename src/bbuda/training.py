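"""Supervised source training and black-box target adaptation.

``train_source`` fits a network on labeled source images with pixel-wise
cross-entropy, holding out a slice of the training set for best-checkpoint
selection.  ``adapt_target`` trains a (possibly different-backbone) target
network against a sealed source model using EMD pseudo labels, KL
distillation and decayed entropy minimization; the adaptation loss never
sees target labels, and a small labeled target-val split is used only to
retain the best checkpoint.

Both loops are deterministic given their seed on a single-threaded CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .backbones import BackboneConfig, build_network
from .blackbox import BlackBoxPredictor
from .engine import Adam, UNet
from .losses import (
    ScheduleState,
    alpha_schedule,
    cross_entropy_loss,
    emd_lambda,
    mixup_pseudo_label,
    total_loss,
)
from .metrics import evaluate, mean_region_dsc


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    seed: int = 0
    lambda0: float = 1.0
    lambda_decay_rate: float = 1.0
    lambda_frozen: bool = False
    pseudo_label_stop_gradient: bool = True
    alpha0: float = 5.0
    alpha_mode: str = "linear"
    warmup_epochs: int = 5
    augment: bool = False
    ce_scale_by_classes: bool = True
    kl_direction: str = "forward"
    val_fraction: float = 0.2
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class RunHistory:
    records: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dsc: float = float("nan")
    checkpoint_path: str | None = None

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def save(self, out_dir: str | Path, name: str = "history") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / f"{name}.csv", index=False)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _dihedral(arrays: list[np.ndarray], rng: np.random.Generator):
    """Apply one random rotation/flip from the dihedral group to each array's
    trailing two (spatial) axes; labels and probability maps stay aligned."""
    k = int(rng.integers(4))
    flip = bool(rng.integers(2))
    out = []
    for a in arrays:
        b = np.rot90(a, k, axes=(-2, -1))
        if flip:
            b = np.flip(b, axis=-1)
        out.append(np.ascontiguousarray(b))
    return out


def _snapshot(net: UNet) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in net.state_arrays().items()}


# --------------------------------------------------------------------------
# supervised source training
# --------------------------------------------------------------------------


def train_source(
    net: UNet,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
) -> tuple[UNet, RunHistory]:
    """Minimize pixel-wise CE on labeled images; keep the best-val weights."""
    if len(images) == 0:
        raise ValueError("empty source training set")
    if labels.max() >= net.n_classes:
        raise ValueError("label classes exceed the network's class count")
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.val_fraction * len(images)))) \
        if len(images) > 1 else 0
    perm = np.random.default_rng(config.seed + 1).permutation(len(images))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    xtr, ytr = images[train_idx], labels[train_idx]
    xval, yval = images[val_idx], labels[val_idx]

    opt = Adam(net.params(), lr=config.learning_rate,
               beta1=config.adam_beta1, beta2=config.adam_beta2)
    history = RunHistory()
    best = _snapshot(net)
    best_dsc, best_epoch = -1.0, -1
    for epoch in range(config.epochs):
        losses = []
        for idx in _batches(len(xtr), config.batch_size, rng):
            xb, yb = xtr[idx], ytr[idx]
            if config.augment:
                xb, yb = _dihedral([xb, yb], rng)
            probs = net.forward(xb, train=True)
            loss, grad = cross_entropy_loss(
                probs, yb, scale_by_classes=config.ce_scale_by_classes,
                return_grad=True,
            )
            net.backward(grad)
            opt.step()
            losses.append(loss)
        val_dsc = float("nan")
        if len(xval):
            report = evaluate(net, xval, yval)
            val_dsc = mean_region_dsc(report, "WholeT")
            if val_dsc > best_dsc:
                best_dsc, best_epoch, best = val_dsc, epoch, _snapshot(net)
        history.append(epoch=epoch, ce_loss=float(np.mean(losses)),
                       val_wholet_dsc=val_dsc)
    if best_epoch >= 0:
        net.load_state_arrays(best)
        history.best_epoch, history.best_val_dsc = best_epoch, best_dsc
    return net, history


# --------------------------------------------------------------------------
# target initialization
# --------------------------------------------------------------------------


def init_target_from_blackbox_or_scratch(
    config: BackboneConfig,
    train_config: TrainConfig,
    bb: BlackBoxPredictor | None = None,
    target_images: np.ndarray | None = None,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> UNet:
    """Build the target backbone; optionally warm it up on hard pseudo labels.

    The black-box setting forbids copying source weights, so the target
    starts from scratch.  With ``warmup_epochs > 0`` and a black box given,
    the fresh network is briefly trained with CE on the argmax of the source
    predictions, so its own predictions are non-degenerate when they enter
    the EMD mixup.  If a labeled target-val split is provided, the
    best-validation warm-up epoch is retained (model selection only; the
    warm-up loss never sees target labels).
    """
    net = build_network(config)
    if bb is None or train_config.warmup_epochs <= 0:
        return net
    if target_images is None or len(target_images) == 0:
        raise ValueError("warm-up requires target images")
    hard = np.concatenate([
        bb.predict(target_images[i : i + train_config.batch_size]).argmax(axis=1)
        for i in range(0, len(target_images), train_config.batch_size)
    ])
    rng = np.random.default_rng(train_config.seed + 17)
    opt = Adam(net.params(), lr=train_config.learning_rate,
               beta1=train_config.adam_beta1, beta2=train_config.adam_beta2)
    track_val = val_images is not None and len(val_images) > 0
    best, best_dsc = None, -1.0
    for _ in range(train_config.warmup_epochs):
        for idx in _batches(len(target_images), train_config.batch_size, rng):
            xb, yb = target_images[idx], hard[idx]
            if train_config.augment:
                xb, yb = _dihedral([xb, yb], rng)
            probs = net.forward(xb, train=True)
            _, grad = cross_entropy_loss(
                probs, yb,
                scale_by_classes=train_config.ce_scale_by_classes,
                return_grad=True,
            )
            net.backward(grad)
            opt.step()
        if track_val:
            report = evaluate(net, val_images, val_labels)
            val_dsc = mean_region_dsc(report, "WholeT")
            if val_dsc > best_dsc:
                best_dsc, best = val_dsc, _snapshot(net)
    if best is not None:
        net.load_state_arrays(best)
    return net


# --------------------------------------------------------------------------
# black-box adaptation
# --------------------------------------------------------------------------


def adapt_target(
    bb: BlackBoxPredictor,
    target_net: UNet,
    target_images: np.ndarray,
    config: TrainConfig,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    cache_source_predictions: bool = True,
) -> tuple[UNet, RunHistory]:
    """Adapt ``target_net`` to unlabeled target images via the sealed source.

    Per epoch ``I``: lambda = lambda0 * exp(-gamma I) (frozen at lambda0
    under the ``lambda_frozen`` ablation) and alpha follows the configured
    schedule; per batch the EMD pseudo label mixes the black box's
    prediction with the network's own, and one Adam step minimizes
    ``L_KL + alpha * L_Ent``.  Source predictions are static, so they are
    queried once and cached by default.
    """
    if len(target_images) == 0:
        raise ValueError("empty adaptation set: no unlabeled target images")
    if target_images.shape[1] != bb.n_channels_in:
        raise ValueError("channel mismatch between target data and black box")
    rng = np.random.default_rng(config.seed)
    opt = Adam(target_net.params(), lr=config.learning_rate,
               beta1=config.adam_beta1, beta2=config.adam_beta2)
    history = RunHistory()

    cached_source = None
    if cache_source_predictions:
        cached_source = np.concatenate([
            bb.predict(target_images[i : i + config.batch_size])
            for i in range(0, len(target_images), config.batch_size)
        ])

    best = _snapshot(target_net)
    best_dsc, best_epoch = -1.0, -1
    for epoch in range(config.epochs):
        state = ScheduleState(
            iteration=epoch, total_epochs=config.epochs,
            lambda0=config.lambda0, decay_rate=config.lambda_decay_rate,
            alpha0=config.alpha0, alpha_mode=config.alpha_mode,
        )
        lam = config.lambda0 if config.lambda_frozen else emd_lambda(state)
        alpha = alpha_schedule(state)
        kl_sum, ent_sum, tot_sum, nb = 0.0, 0.0, 0.0, 0
        for idx in _batches(len(target_images), config.batch_size, rng):
            if cached_source is not None:
                src = cached_source[idx]
            else:
                src = bb.predict(target_images[idx])
            xb = target_images[idx]
            if config.augment:
                xb, src = _dihedral([xb, src], rng)
            probs = target_net.forward(xb, train=True)
            pseudo = mixup_pseudo_label(src, probs, lam)
            if config.pseudo_label_stop_gradient:
                tot, comps, grad = total_loss(
                    probs, pseudo, state, return_grad=True,
                    kl_direction=config.kl_direction,
                )
            else:
                from .losses import (
                    alpha_schedule as _alpha,
                    entropy_loss as _ent,
                    kl_distillation_loss_through_mixup as _klm,
                )

                kl, gkl = _klm(probs, src, lam, return_grad=True)
                ent, gent = _ent(probs, return_grad=True)
                a = _alpha(state)
                tot = kl + a * ent
                grad = gkl + a * gent
                comps = {"kl": kl, "entropy": ent, "alpha": a,
                         "lambda": lam, "total": tot}
            target_net.backward(grad)
            opt.step()
            kl_sum += comps["kl"]
            ent_sum += comps["entropy"]
            tot_sum += tot
            nb += 1
        val_dsc = float("nan")
        if val_images is not None and len(val_images):
            report = evaluate(target_net, val_images, val_labels)
            val_dsc = mean_region_dsc(report, "WholeT")
            if val_dsc > best_dsc:
                best_dsc, best_epoch = val_dsc, epoch
                best = _snapshot(target_net)
        history.append(
            epoch=epoch, lam=lam, alpha=alpha,
            kl_loss=kl_sum / nb, entropy_loss=ent_sum / nb,
            total_loss=tot_sum / nb, val_wholet_dsc=val_dsc,
        )
    if best_epoch >= 0:
        target_net.load_state_arrays(best)
        history.best_epoch, history.best_val_dsc = best_epoch, best_dsc
    return target_net, history


def save_run(out_dir: str | Path, history: RunHistory, config: TrainConfig,
             name: str = "history") -> None:
    """Persist a run: per-epoch CSV plus a JSON manifest of the config."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    history.save(out, name=name)
    (out / f"{name}_config.json").write_text(json.dumps(asdict(config), indent=2))
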