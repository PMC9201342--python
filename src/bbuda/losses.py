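"""Training objectives and their decay schedules.

All losses operate on per-pixel class-probability maps of shape
``(N, C, H, W)`` (the networks' softmax outputs) and return a scalar mean
over every pixel of every image in the batch.  Functions used during
training also return the gradient with respect to the target-network
probabilities, which the engine backpropagates through its softmax head.

The adaptation objective is

    L = L_KL + alpha(I) * L_Ent

where ``L_KL`` distills the exponential-mixup-decay (EMD) pseudo label

    y' = lambda * f_s(x_t) + (1 - lambda) * f_t(x_t),
    lambda(I) = lambda0 * exp(-gamma * I)

into the target network via KL(f_t(x_t) || y'), and ``L_Ent`` is the mean
per-pixel self-entropy with weight ``alpha`` decayed linearly from
``alpha0`` (default 5) to 0 over training.

The decay index ``I`` counts epochs.  Counting raw mini-batch iterations
would drive ``lambda`` to zero within a handful of batches, contradicting
the intended behavior of a source weight that is large early in training
and small in the later epochs; the unit and the rate ``gamma`` are
config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-8


# --------------------------------------------------------------------------
# schedules
# --------------------------------------------------------------------------


@dataclass
class ScheduleState:
    """Decay state: epoch index, horizon, and schedule hyperparameters.

    ``alpha_mode``: ``linear`` (alpha0 -> 0), ``constant`` (always alpha0)
    or ``zero`` (entropy term off) — the latter two for ablations.
    """

    iteration: int = 0
    total_epochs: int = 1
    lambda0: float = 1.0
    decay_rate: float = 1.0
    alpha0: float = 5.0
    alpha_mode: str = "linear"

    def __post_init__(self):
        if self.iteration < 0:
            raise ValueError("iteration must be >= 0")
        if self.total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be > 0")
        if self.alpha_mode not in ("linear", "constant", "zero"):
            raise ValueError("alpha_mode must be linear|constant|zero")


def emd_lambda(state: ScheduleState) -> float:
    """Source-prediction weight: lambda0 * exp(-gamma * I)."""
    return float(state.lambda0 * np.exp(-state.decay_rate * state.iteration))


def alpha_schedule(state: ScheduleState) -> float:
    """Entropy weight: alpha0 * (1 - I/E), clamped at 0 (linear mode)."""
    if state.alpha_mode == "zero":
        return 0.0
    if state.alpha_mode == "constant":
        return float(state.alpha0)
    return float(state.alpha0 * max(0.0, 1.0 - state.iteration / state.total_epochs))


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def _clamp_renorm(p: np.ndarray) -> np.ndarray:
    """Clamp probabilities to [EPS, 1] and renormalize over classes."""
    p = np.clip(p, EPS, 1.0)
    return p / p.sum(axis=1, keepdims=True)


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p)
    if p.ndim != 4:
        raise ValueError("probability maps must have shape (N, C, H, W)")
    return p


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------


def cross_entropy_loss(
    pred: np.ndarray,
    label: np.ndarray,
    scale_by_classes: bool = True,
    return_grad: bool = False,
):
    """Pixel-wise cross-entropy of probability maps against integer labels.

    With ``scale_by_classes`` (default) the per-pixel term is
    ``-(1/C) * log p_true``, i.e. the one-hot sum carries a 1/C factor; this
    rescales the loss without moving its argmin.  Set it to False for the
    conventional unscaled CE.
    """
    pred = _check_probs(pred)
    n, c, h, w = pred.shape
    label = np.asarray(label)
    if label.shape != (n, h, w):
        raise ValueError("label shape must be (N, H, W)")
    if label.min() < 0 or label.max() >= c:
        raise ValueError("label contains invalid class indices")
    scale = (1.0 / c) if scale_by_classes else 1.0
    npix = n * h * w
    ii, rr, cc = np.indices(label.shape, sparse=False).reshape(3, -1)
    ptrue = pred[ii, label.ravel(), rr, cc]
    value = float(scale * -np.log(np.clip(ptrue, EPS, 1.0)).sum() / npix)
    if not return_grad:
        return value
    grad = np.zeros_like(pred)
    g = -scale / (np.clip(ptrue, EPS, 1.0) * npix)
    grad[ii, label.ravel(), rr, cc] = g
    return value, grad


def mixup_pseudo_label(
    source_probs: np.ndarray, target_probs: np.ndarray, lam: float
) -> np.ndarray:
    """EMD pseudo label: ``lam * f_s(x_t) + (1 - lam) * f_t(x_t)``.

    The result is a fresh array, detached from any training state: the
    pseudo label is a constant during gradient computation (self-training).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    source_probs = _check_probs(source_probs)
    target_probs = _check_probs(target_probs)
    if source_probs.shape != target_probs.shape:
        raise ValueError("source and target probability shapes differ")
    return np.array(lam * source_probs + (1.0 - lam) * target_probs, copy=True)


def kl_distillation_loss(
    target_probs: np.ndarray, pseudo: np.ndarray, return_grad: bool = False
):
    """Mean per-pixel KL(f_t(x_t) || y') against the EMD pseudo label.

    The forward direction (target prediction first) penalizes target mass
    placed where the pseudo label has none; gradient flows only through
    ``target_probs``.
    """
    target_probs = _check_probs(target_probs)
    pseudo = _check_probs(pseudo)
    if target_probs.shape != pseudo.shape:
        raise ValueError("shape mismatch between target probs and pseudo label")
    n, c, h, w = target_probs.shape
    npix = n * h * w
    q = _clamp_renorm(target_probs)
    y = _clamp_renorm(pseudo)
    logratio = np.log(q) - np.log(y)
    value = float((q * logratio).sum() / npix)
    if not return_grad:
        return value
    # d/dq of sum q log(q/y) = log(q/y) + 1; the softmax backward removes
    # the constant, and the clamp/renorm Jacobian is ~identity away from
    # the floor, so this is the exact gradient in the interior.
    grad = (logratio + 1.0) / npix
    return value, grad


def kl_distillation_loss_through_mixup(
    target_probs: np.ndarray,
    source_probs: np.ndarray,
    lam: float,
    return_grad: bool = False,
):
    """KL(f_t || y') with gradient flowing through BOTH arguments.

    Here y' = lam*f_s + (1-lam)*f_t is *not* detached: since y'_i depends on
    q_i only, d/dq_i = log(q_i/y'_i) + 1 - (1-lam)*q_i/y'_i.  Off by
    default (the pseudo label is a self-training constant); provided to
    study what the stop-gradient contributes.
    """
    q = _clamp_renorm(_check_probs(target_probs))
    s = _clamp_renorm(_check_probs(source_probs))
    n, c, h, w = q.shape
    npix = n * h * w
    y = lam * s + (1.0 - lam) * q
    logratio = np.log(q) - np.log(y)
    value = float((q * logratio).sum() / npix)
    if not return_grad:
        return value
    grad = (logratio + 1.0 - (1.0 - lam) * q / y) / npix
    return value, grad


def entropy_loss(target_probs: np.ndarray, return_grad: bool = False):
    """Mean per-pixel Shannon entropy of the prediction."""
    target_probs = _check_probs(target_probs)
    n, c, h, w = target_probs.shape
    npix = n * h * w
    q = _clamp_renorm(target_probs)
    logq = np.log(q)
    value = float(-(q * logq).sum() / npix)
    if not return_grad:
        return value
    grad = -(logq + 1.0) / npix
    return value, grad


def reverse_kl_distillation_loss(target_probs, pseudo, return_grad=False):
    """KL(y' || f_t(x_t)): the opposite distillation direction (study flag)."""
    target_probs = _check_probs(target_probs)
    pseudo = _check_probs(pseudo)
    n, c, h, w = target_probs.shape
    npix = n * h * w
    q = _clamp_renorm(target_probs)
    y = _clamp_renorm(pseudo)
    value = float((y * (np.log(y) - np.log(q))).sum() / npix)
    if not return_grad:
        return value
    grad = -(y / q) / npix
    return value, grad


def total_loss(
    target_probs: np.ndarray,
    pseudo: np.ndarray,
    state: ScheduleState,
    return_grad: bool = False,
    kl_direction: str = "forward",
):
    """Combined objective ``L_KL + alpha(I) * L_Ent`` with components.

    Returns ``(total, components)`` or ``(total, components, grad)``, where
    components is a dict with ``kl``, ``entropy``, ``alpha`` and ``lambda``.
    """
    alpha = alpha_schedule(state)
    kl_fn = (kl_distillation_loss if kl_direction == "forward"
             else reverse_kl_distillation_loss)
    if return_grad:
        kl, gkl = kl_fn(target_probs, pseudo, return_grad=True)
        ent, gent = entropy_loss(target_probs, return_grad=True)
    else:
        kl = kl_fn(target_probs, pseudo)
        ent = entropy_loss(target_probs)
    total = kl + alpha * ent
    components = {
        "kl": kl,
        "entropy": ent,
        "alpha": alpha,
        "lambda": emd_lambda(state),
        "total": total,
    }
    if not return_grad:
        return total, components
    return total, components, gkl + alpha * gent
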