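"""Image/mask I/O, the class index/colour convention, and dataset splitting.

All images are 8-bit grayscale PNGs rescaled to ``[0, 1]`` floats and resized
to a fixed square working resolution (400 px by default, matching the network
input).  Label masks are dense integer arrays over the five blastocyst
classes and can be stored either as single-channel index PNGs or as RGB
colour-coded PNGs using the conventional display colours (TE red, ZP green,
ICM blue, BL yellow, background black).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "CLASS_MAP",
    "ClassMap",
    "DatasetManifest",
    "ImageSample",
    "ManifestRecord",
    "read_sample",
    "split_dataset",
    "write_image",
    "write_mask",
]

DEFAULT_IMAGE_SIZE = 400


@dataclass(frozen=True)
class ClassMap:
    """Ordered mapping between class names, integer indices and RGB colours.

    The canonical instance :data:`CLASS_MAP` fixes BG=0 (black), TE=1 (red),
    ZP=2 (green), ICM=3 (blue), BL=4 (yellow).
    """

    entries: tuple[tuple[str, int, tuple[int, int, int]], ...]

    def __post_init__(self) -> None:
        indices = [idx for _, idx, _ in self.entries]
        names = [name for name, _, _ in self.entries]
        colors = [c for _, _, c in self.entries]
        if sorted(indices) != list(range(len(self.entries))):
            raise ValueError(f"class indices must be exactly 0..{len(self.entries) - 1}")
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        if len(set(colors)) != len(colors):
            raise ValueError("class colours must be unique")

    @property
    def n_classes(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in sorted(self.entries, key=lambda e: e[1]))

    def index_of(self, name: str) -> int:
        for n, idx, _ in self.entries:
            if n == name:
                return idx
        raise KeyError(name)

    def color_of(self, index: int) -> tuple[int, int, int]:
        for _, idx, c in self.entries:
            if idx == index:
                return c
        raise KeyError(index)

    def palette(self) -> np.ndarray:
        """(n_classes, 3) uint8 array mapping index -> RGB colour."""
        pal = np.zeros((self.n_classes, 3), dtype=np.uint8)
        for _, idx, c in self.entries:
            pal[idx] = c
        return pal


#: Canonical five-class convention: BG=0, TE=1, ZP=2, ICM=3, BL=4.
CLASS_MAP = ClassMap(
    entries=(
        ("BG", 0, (0, 0, 0)),
        ("TE", 1, (255, 0, 0)),
        ("ZP", 2, (0, 255, 0)),
        ("ICM", 3, (0, 0, 255)),
        ("BL", 4, (255, 255, 0)),
    )
)


@dataclass
class ImageSample:
    """One grayscale image plus its dense integer label mask."""

    image: np.ndarray  # float array in [0, 1], shape (H, W)
    mask: np.ndarray  # integer array, shape (H, W), values in class indices
    sample_id: str = ""

    def validate(self, class_map: ClassMap = CLASS_MAP) -> "ImageSample":
        if self.image.ndim != 2 or self.mask.ndim != 2:
            raise ValueError("image and mask must be 2-D arrays")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        bad = np.setdiff1d(np.unique(self.mask), np.arange(class_map.n_classes))
        if bad.size:
            raise ValueError(f"mask contains unknown class value(s) {bad.tolist()}")
        return self


@dataclass
class ManifestRecord:
    sample_id: str
    image_path: str
    mask_path: str
    split: Literal["train", "test"]


@dataclass
class DatasetManifest:
    """List of (sample_id, image_path, mask_path, split) records."""

    records: list[ManifestRecord] = field(default_factory=list)
    split_seed: int = 0

    def ids(self, split: str | None = None) -> list[str]:
        return [r.sample_id for r in self.records if split is None or r.split == split]

    def subset(self, split: str) -> list[ManifestRecord]:
        return [r for r in self.records if r.split == split]

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample_id", "image_path", "mask_path", "split"])
            for r in self.records:
                writer.writerow([r.sample_id, r.image_path, r.mask_path, r.split])

    @classmethod
    def read_csv(cls, path: str | Path, split_seed: int = 0) -> "DatasetManifest":
        records = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                records.append(
                    ManifestRecord(
                        sample_id=row["sample_id"],
                        image_path=row["image_path"],
                        mask_path=row["mask_path"],
                        split=row["split"],  # type: ignore[arg-type]
                    )
                )
        return cls(records=records, split_seed=split_seed)


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) array to grayscale by channel averaging."""
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return arr


def _resize_image(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a [0,1] float image to size x size."""
    if img.shape == (size, size):
        return img
    pil = Image.fromarray((np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8))
    out = pil.resize((size, size), Image.BILINEAR)
    return np.asarray(out, dtype=np.float64) / 255.0


def _resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour resize; never invents labels absent from the source."""
    if mask.shape == (size, size):
        return mask
    pil = Image.fromarray(mask.astype(np.uint8))
    out = pil.resize((size, size), Image.NEAREST)
    return np.asarray(out, dtype=np.int64)


def _decode_mask(arr: np.ndarray, class_map: ClassMap) -> np.ndarray:
    """Decode an index-coded or colour-coded mask array to class indices."""
    if arr.ndim == 2:
        mask = arr.astype(np.int64)
        bad = np.setdiff1d(np.unique(mask), np.arange(class_map.n_classes))
        if bad.size:
            raise ValueError(f"mask contains unknown class index value(s) {bad.tolist()}")
        return mask
    rgb = arr[..., :3].astype(np.int64)
    mask = np.full(rgb.shape[:2], -1, dtype=np.int64)
    for _, idx, color in class_map.entries:
        hit = np.all(rgb == np.asarray(color), axis=2)
        mask[hit] = idx
    if (mask < 0).any():
        offending = rgb[mask < 0][0]
        raise ValueError(f"mask contains unknown colour {tuple(offending.tolist())}")
    return mask


def read_sample(
    image_path: str | Path,
    mask_path: str | Path,
    class_map: ClassMap = CLASS_MAP,
    size: int = DEFAULT_IMAGE_SIZE,
    sample_id: str | None = None,
) -> ImageSample:
    """Read one image/mask pair, rescale intensities to [0,1] and resize.

    The image is resized bilinearly, the mask with nearest-neighbour
    interpolation so no new labels can be introduced.  Colour-coded masks are
    translated to indices via ``class_map``; any pixel value outside the
    convention is a hard error.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    img_arr = np.asarray(Image.open(image_path), dtype=np.float64)
    img = _to_grayscale(img_arr) / 255.0
    mask = _decode_mask(np.asarray(Image.open(mask_path)), class_map)
    if img.shape != mask.shape:
        raise ValueError(
            f"image shape {img.shape} != mask shape {mask.shape} "
            f"for {image_path.name}/{mask_path.name}"
        )
    img = _resize_image(img, size)
    mask = _resize_mask(mask, size)
    sid = sample_id if sample_id is not None else image_path.stem
    return ImageSample(image=img, mask=mask, sample_id=sid).validate(class_map)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0,1] float image as an 8-bit grayscale PNG."""
    arr = (np.clip(image, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def write_mask(
    mask: np.ndarray,
    path: str | Path,
    mode: Literal["index", "color"] = "index",
    class_map: ClassMap = CLASS_MAP,
) -> None:
    """Write a label mask as an index PNG (one 8-bit channel) or RGB PNG.

    Index mode round-trips exactly through :func:`read_sample`.
    """
    bad = np.setdiff1d(np.unique(mask), np.arange(class_map.n_classes))
    if bad.size:
        raise ValueError(f"mask contains unknown class value(s) {bad.tolist()}")
    if mode == "index":
        Image.fromarray(mask.astype(np.uint8), mode="L").save(Path(path))
    elif mode == "color":
        rgb = class_map.palette()[mask.astype(np.int64)]
        Image.fromarray(rgb, mode="RGB").save(Path(path))
    else:
        raise ValueError(f"unknown mask mode {mode!r}")


def split_dataset(
    sample_ids: Sequence[str] | Iterable[str],
    train_fraction: float = 0.85,
    seed: int = 0,
) -> DatasetManifest:
    """Deterministically partition sample ids into train/test splits.

    ``|train| = round(train_fraction * N)``; e.g. 235 samples at 0.85 give
    the conventional 200 train / 35 test division.
    """
    ids = list(sample_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("sample_ids must be unique")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(ids) < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)  # both splits non-empty
    train_ids = {ids[i] for i in order[:n_train]}
    records = [
        ManifestRecord(
            sample_id=sid,
            image_path=f"{sid}_image.png",
            mask_path=f"{sid}_mask.png",
            split="train" if sid in train_ids else "test",
        )
        for sid in ids
    ]
    return DatasetManifest(records=records, split_seed=seed)
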