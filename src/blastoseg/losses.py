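"""Training losses over 5-class softmax probabilities.

Four losses are provided, all averaged over classes so their magnitudes are
comparable in ablation runs:

* ``tvl`` — Tversky loss, the default.  Per class ``c`` the Tversky index is
  ``TI_c = (sum p g + s) / (sum p g + alpha * sum p (1-g) + beta * sum (1-p) g + s)``
  and the loss is ``mean_c (1 - TI_c)``.  ``alpha`` weights false positives,
  ``beta`` false negatives; ``alpha = beta = 0.5`` recovers the Dice loss.
  The asymmetry is what lets minority classes (ICM, TE, ZP) compete with the
  dominant background/blastocoel pixels.
* ``dl`` — Dice loss, ``mean_c (1 - (2 sum p g + s) / (sum p + sum g + s))``.
* ``wce`` — weighted cross-entropy with per-class weights (default: inverse
  pixel-frequency weights normalised to mean 1 over the training set).
* ``fl`` — focal loss ``-mean_i sum_c g (1-p)^gamma log p`` with
  ``gamma = 2`` by default; ``gamma = 0`` is plain cross-entropy.

Each loss also has an analytic gradient with respect to the pre-softmax
scores, used by the training loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import N_CLASSES

__all__ = [
    "LossConfig",
    "dice_loss",
    "focal_loss",
    "inverse_frequency_weights",
    "loss_and_score_grad",
    "one_hot",
    "softmax",
    "tversky_loss",
    "weighted_cross_entropy",
]

LOSS_KINDS = ("tvl", "wce", "fl", "dl")


@dataclass
class LossConfig:
    kind: str = "tvl"
    alpha: float = 0.7  # Tversky false-positive weight
    beta: float = 0.3  # Tversky false-negative weight
    gamma: float = 2.0  # focal exponent
    class_weights: np.ndarray = field(
        default_factory=lambda: np.ones(N_CLASSES, dtype=np.float64)
    )
    smooth: float = 1e-6

    def __post_init__(self) -> None:
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}; choose from {LOSS_KINDS}")
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("alpha, beta and gamma must be >= 0")
        if self.smooth <= 0:
            raise ValueError("smooth must be > 0")
        self.class_weights = np.asarray(self.class_weights, dtype=np.float64)
        if self.class_weights.shape != (N_CLASSES,) or (self.class_weights < 0).any():
            raise ValueError(f"class_weights must be {N_CLASSES} nonnegative reals")


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(mask: np.ndarray, n_classes: int = N_CLASSES, dtype=np.float32) -> np.ndarray:
    """(..., H, W) integer mask -> (..., C, H, W) one-hot target."""
    eye = np.eye(n_classes, dtype=dtype)
    oh = eye[mask]  # (..., H, W, C)
    return np.moveaxis(oh, -1, -3)


def inverse_frequency_weights(masks: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Inverse class pixel-frequency weights, normalised to mean 1.

    Classes absent from the training masks receive the weight of the rarest
    present class.
    """
    if isinstance(masks, np.ndarray):
        masks = [masks]
    counts = np.zeros(N_CLASSES, dtype=np.float64)
    for m in masks:
        counts += np.bincount(np.ravel(m), minlength=N_CLASSES)
    total = counts.sum()
    with np.errstate(divide="ignore"):
        w = np.where(counts > 0, total / np.maximum(counts, 1), 0.0)
    if (counts == 0).any():
        w[counts == 0] = w[counts > 0].max()
    return w / w.mean()


def _check(probs: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if probs.shape != target.shape:
        raise ValueError(f"probs shape {probs.shape} != target shape {target.shape}")
    if probs.ndim == 3:
        probs, target = probs[None], target[None]
    if probs.ndim != 4:
        raise ValueError("expected (N, C, H, W) or (C, H, W) arrays")
    return probs, target


def _class_sums(probs, target):
    axes = (0, 2, 3)
    inter = (probs * target).sum(axis=axes)
    p_not_g = (probs * (1.0 - target)).sum(axis=axes)  # false-positive mass
    g_not_p = ((1.0 - probs) * target).sum(axis=axes)  # false-negative mass
    return inter, p_not_g, g_not_p


def tversky_loss(probs: np.ndarray, target: np.ndarray, config: LossConfig | None = None) -> float:
    """Mean over classes of ``1 - TI_c`` with batch-pooled pixel sums."""
    config = config or LossConfig(kind="tvl")
    probs, target = _check(probs, target)
    inter, pn, gn = _class_sums(probs, target)
    s = config.smooth
    ti = (inter + s) / (inter + config.alpha * pn + config.beta * gn + s)
    return float(np.mean(1.0 - ti))


def dice_loss(probs: np.ndarray, target: np.ndarray, config: LossConfig | None = None) -> float:
    """Mean over classes of ``1 - DSC_c``."""
    config = config or LossConfig(kind="dl")
    probs, target = _check(probs, target)
    axes = (0, 2, 3)
    inter = (probs * target).sum(axis=axes)
    s = config.smooth
    dsc = (2.0 * inter + s) / (probs.sum(axis=axes) + target.sum(axis=axes) + s)
    return float(np.mean(1.0 - dsc))


def weighted_cross_entropy(
    probs: np.ndarray, target: np.ndarray, config: LossConfig | None = None
) -> float:
    """``-mean_pixels sum_c w_c g_c log(p_c)``, probabilities clamped by smooth."""
    config = config or LossConfig(kind="wce")
    probs, target = _check(probs, target)
    w = config.class_weights[None, :, None, None]
    logp = np.log(np.maximum(probs, config.smooth))
    n_pix = probs.shape[0] * probs.shape[2] * probs.shape[3]
    return float(-(w * target * logp).sum() / n_pix)


def focal_loss(probs: np.ndarray, target: np.ndarray, config: LossConfig | None = None) -> float:
    """``-mean_pixels sum_c g_c (1 - p_c)^gamma log(p_c)``."""
    config = config or LossConfig(kind="fl")
    probs, target = _check(probs, target)
    logp = np.log(np.maximum(probs, config.smooth))
    mod = (1.0 - probs) ** config.gamma
    n_pix = probs.shape[0] * probs.shape[2] * probs.shape[3]
    return float(-(target * mod * logp).sum() / n_pix)


_LOSS_FNS = {
    "tvl": tversky_loss,
    "dl": dice_loss,
    "wce": weighted_cross_entropy,
    "fl": focal_loss,
}


def compute_loss(probs: np.ndarray, target: np.ndarray, config: LossConfig) -> float:
    return _LOSS_FNS[config.kind](probs, target, config)


def _grad_probs(probs: np.ndarray, target: np.ndarray, config: LossConfig) -> np.ndarray:
    """dLoss/dprobs for the configured loss (float64, batch layout)."""
    c = probs.shape[1]
    if config.kind == "tvl":
        inter, pn, gn = _class_sums(probs, target)
        s = config.smooth
        num = inter + s
        den = inter + config.alpha * pn + config.beta * gn + s
        # d num/dp = g ; d den/dp = g + alpha(1-g) - beta g
        dden = target + config.alpha * (1.0 - target) - config.beta * target
        dti = (target * den[None, :, None, None] - num[None, :, None, None] * dden) / (
            den[None, :, None, None] ** 2
        )
        return -dti / c
    if config.kind == "dl":
        axes = (0, 2, 3)
        inter = (probs * target).sum(axis=axes)
        psum = probs.sum(axis=axes)
        gsum = target.sum(axis=axes)
        s = config.smooth
        num = 2.0 * inter + s
        den = psum + gsum + s
        ddsc = (2.0 * target * den[None, :, None, None] - num[None, :, None, None]) / (
            den[None, :, None, None] ** 2
        )
        return -ddsc / c
    n_pix = probs.shape[0] * probs.shape[2] * probs.shape[3]
    clamped = np.maximum(probs, config.smooth)
    active = (probs >= config.smooth).astype(probs.dtype)  # log clamp kills the grad below it
    if config.kind == "wce":
        w = config.class_weights[None, :, None, None]
        return -(w * target * active / clamped) / n_pix
    if config.kind == "fl":
        g = config.gamma
        logp = np.log(clamped)
        mod = (1.0 - probs) ** g
        dmod = -g * (1.0 - probs) ** (g - 1.0) if g > 0 else 0.0
        return -(target * (dmod * logp + mod * active / clamped)) / n_pix
    raise ValueError(config.kind)  # pragma: no cover


def loss_and_score_grad(
    scores: np.ndarray, target: np.ndarray, config: LossConfig
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. the pre-softmax scores.

    The softmax Jacobian is applied analytically:
    ``dL/dz_c = p_c (dL/dp_c - sum_k dL/dp_k p_k)``.
    """
    probs = softmax(np.asarray(scores, dtype=np.float64), axis=1)
    target = np.asarray(target, dtype=np.float64)
    value = compute_loss(probs, target, config)
    gp = _grad_probs(probs, target, config)
    dot = (gp * probs).sum(axis=1, keepdims=True)
    dz = probs * (gp - dot)
    return value, dz.astype(scores.dtype, copy=False)
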