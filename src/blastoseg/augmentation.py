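"""Paired geometric augmentation of image/mask samples.

Each transform applies the identical geometric map to the image (bilinear
interpolation) and the mask (nearest-neighbour), so annotations stay aligned.
Pixels entering the frame from outside are filled with the background gray
level in the image and with the BG label in the mask — background is the only
class that can legitimately surround the embryo.

The expansion factor defaults to 16 (e.g. 200 training images -> 3200), with
the untouched original occupying the first of the 16 slots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dataio import CLASS_MAP, ImageSample

__all__ = ["TransformSpec", "apply_transform", "augment_dataset", "default_bank"]

_KINDS = frozenset({"identity", "hflip", "vflip", "rotate", "translate"})

#: Image fill value for pixels entering from outside the frame; matches the
#: default phantom background gray level.
BG_FILL = 0.55
BG_LABEL = CLASS_MAP.index_of("BG")


@dataclass(frozen=True)
class TransformSpec:
    """One geometric transform: identity, flips, rotate(angle°) or translate(dx, dy)."""

    kind: str
    angle: float = 0.0  # degrees, counter-clockwise; rotate only
    dx: int = 0  # px, translate only
    dy: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if not np.isfinite(self.angle):
            raise ValueError("rotation angle must be finite")


def apply_transform(
    sample: ImageSample, transform: TransformSpec, bg_fill: float = BG_FILL
) -> ImageSample:
    """Apply one transform to image and mask with the same geometric map."""
    img, mask = sample.image, sample.mask
    t = transform
    if t.kind == "identity":
        new_img, new_mask = img.copy(), mask.copy()
    elif t.kind == "hflip":
        new_img, new_mask = img[:, ::-1].copy(), mask[:, ::-1].copy()
    elif t.kind == "vflip":
        new_img, new_mask = img[::-1, :].copy(), mask[::-1, :].copy()
    elif t.kind == "rotate":
        quarter, rem = divmod(t.angle % 360.0, 90.0)
        if rem == 0.0:  # exact right-angle rotations need no resampling
            k = int(quarter)
            new_img, new_mask = np.rot90(img, k).copy(), np.rot90(mask, k).copy()
        else:
            new_img = ndimage.rotate(
                img, t.angle, reshape=False, order=1, mode="constant", cval=bg_fill
            )
            new_mask = ndimage.rotate(
                mask, t.angle, reshape=False, order=0, mode="constant", cval=BG_LABEL
            )
    elif t.kind == "translate":
        h, w = img.shape
        if abs(t.dx) >= w or abs(t.dy) >= h:
            raise ValueError(f"translation ({t.dx},{t.dy}) exceeds image size {w}x{h}")
        new_img = ndimage.shift(img, (t.dy, t.dx), order=1, mode="constant", cval=bg_fill)
        new_mask = ndimage.shift(mask, (t.dy, t.dx), order=0, mode="constant", cval=BG_LABEL)
    else:  # pragma: no cover - guarded by TransformSpec
        raise ValueError(f"unknown transform kind {t.kind!r}")
    new_img = np.clip(new_img, 0.0, 1.0)
    suffix = _suffix(t)
    return ImageSample(
        image=new_img,
        mask=new_mask.astype(np.int64),
        sample_id=f"{sample.sample_id}{suffix}",
    ).validate()


def _suffix(t: TransformSpec) -> str:
    if t.kind == "identity":
        return ""
    if t.kind == "rotate":
        return f"_rot{t.angle:+.0f}"
    if t.kind == "translate":
        return f"_tr{t.dx:+d}{t.dy:+d}"
    return f"_{t.kind}"


def default_bank(translate_px: int = 20) -> list[TransformSpec]:
    """Fixed bank of flips, right-angle and small rotations, and translations."""
    bank = [
        TransformSpec("hflip"),
        TransformSpec("vflip"),
        TransformSpec("rotate", angle=90.0),
        TransformSpec("rotate", angle=180.0),
        TransformSpec("rotate", angle=270.0),
        TransformSpec("rotate", angle=15.0),
        TransformSpec("rotate", angle=-15.0),
    ]
    d = translate_px
    bank += [
        TransformSpec("translate", dx=d),
        TransformSpec("translate", dx=-d),
        TransformSpec("translate", dy=d),
        TransformSpec("translate", dy=-d),
        TransformSpec("translate", dx=d, dy=d),
        TransformSpec("translate", dx=-d, dy=-d),
    ]
    return bank


def _random_transform(rng: np.random.Generator, max_shift: int) -> TransformSpec:
    if rng.random() < 0.5:
        return TransformSpec("rotate", angle=float(rng.uniform(-30.0, 30.0)))
    dx, dy = rng.integers(-max_shift, max_shift + 1, size=2)
    return TransformSpec("translate", dx=int(dx), dy=int(dy))


def augment_dataset(
    train_samples: list[ImageSample],
    factor: int = 16,
    seed: int = 0,
    translate_px: int | None = None,
) -> list[ImageSample]:
    """Expand a training set ``factor``-fold with deterministic transforms.

    Slot 1 of each sample's ``factor`` outputs is the identity; the remaining
    slots are drawn per-sample (seeded by ``seed`` and the sample position)
    from the fixed bank, topped up with random rotations/translations when
    ``factor`` exceeds the bank size.  ``factor=16`` turns 200 inputs into
    the conventional 3200-image training set.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out: list[ImageSample] = []
    for i, sample in enumerate(train_samples):
        size = min(sample.image.shape)
        shift = translate_px if translate_px is not None else max(1, size // 20)
        bank = default_bank(translate_px=shift)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        transforms = [TransformSpec("identity")]
        transforms += bank[: factor - 1]
        while len(transforms) < factor:
            transforms.append(_random_transform(rng, max_shift=shift))
        for j, t in enumerate(transforms[:factor]):
            aug = apply_transform(sample, t)
            aug.sample_id = f"{sample.sample_id}_aug{j:02d}{_suffix(t)}"
            out.append(aug)
    return out
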