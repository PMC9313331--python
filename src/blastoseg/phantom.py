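"""Synthetic blastocyst phantoms with exact ground-truth masks.

A phantom is a roughly circular embryo on a gray background: the zona
pellucida (ZP) forms the outer annulus, the trophectoderm (TE) the annulus
immediately inside it, the blastocoel (BL) fills the cavity, and the inner
cell mass (ICM) is a single blob attached to the inner TE wall.  The class
mean intensities are deliberately close together and the image is blurred
before noise is added, so class boundaries are intensity-ambiguous — the
regime a blastocyst segmentation network actually faces.  Background and BL
dominate the pixel count while ZP/TE/ICM are minor classes, reproducing the
class imbalance the training losses must cope with.

Everything is deterministic given ``(config.seed, sample_index)``, and
independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .dataio import (
    CLASS_MAP,
    DatasetManifest,
    ImageSample,
    ManifestRecord,
    split_dataset,
    write_image,
    write_mask,
)

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset"]

BG, TE, ZP, ICM, BL = (CLASS_MAP.index_of(n) for n in ("BG", "TE", "ZP", "ICM", "BL"))


def _scaled(lo: float, hi: float, size: int) -> tuple[float, float]:
    return (lo * size, hi * size)


@dataclass
class PhantomConfig:
    """Geometry, photometry and noise parameters of the phantom generator.

    Radii/thickness ranges default to fixed fractions of ``image_size`` so a
    phantom looks the same at 400 px (the native working resolution) and at
    reduced desk-scale sizes.  Gray levels are spaced 0.05 apart so that
    neighbouring structures differ by an amount comparable to the blur/noise,
    i.e. boundaries are not trivially separable by intensity.
    """

    image_size: int = 400
    center_jitter: float | None = None  # px; default 0.02 * size
    zp_outer_radius: tuple[float, float] | None = None  # px; default (0.38, 0.45)*size
    zp_thickness: tuple[float, float] | None = None  # px; default (0.05, 0.08)*size
    te_thickness: tuple[float, float] | None = None  # px; default (0.04, 0.06)*size
    icm_radius: tuple[float, float] | None = None  # px; default (0.10, 0.14)*size
    class_gray_levels: dict[str, float] = field(
        default_factory=lambda: {"ICM": 0.45, "TE": 0.50, "BG": 0.55, "BL": 0.60, "ZP": 0.65}
    )
    blur_sigma: float | None = None  # px; default 0.004 * size
    noise_sigma: float = 0.02  # additive Gaussian noise, intensity units
    illumination_gradient: float = 0.05  # peak-to-peak linear shading amplitude
    boundary_wobble: float = 0.15  # radial wobble of ring boundaries, fraction of ZP thickness
    seed: int = 0

    def __post_init__(self) -> None:
        s = self.image_size
        if self.center_jitter is None:
            self.center_jitter = 0.02 * s
        if self.zp_outer_radius is None:
            self.zp_outer_radius = _scaled(0.38, 0.45, s)
        if self.zp_thickness is None:
            self.zp_thickness = _scaled(0.05, 0.08, s)
        if self.te_thickness is None:
            self.te_thickness = _scaled(0.04, 0.06, s)
        if self.icm_radius is None:
            self.icm_radius = _scaled(0.10, 0.14, s)
        if self.blur_sigma is None:
            self.blur_sigma = 0.004 * s
        self.validate()

    def validate(self) -> None:
        for name in ("zp_outer_radius", "zp_thickness", "te_thickness", "icm_radius"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range must be positive and ordered, got ({lo}, {hi})")
        for cname, g in self.class_gray_levels.items():
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"gray level for {cname} must be in [0,1], got {g}")
        if set(self.class_gray_levels) != {"BG", "TE", "ZP", "ICM", "BL"}:
            raise ValueError("class_gray_levels must name exactly BG, TE, ZP, ICM, BL")
        # Worst case: largest rings must still leave a cavity able to host the ICM.
        r_out = self.zp_outer_radius[0]
        cavity = r_out - self.zp_thickness[1] - self.te_thickness[1]
        if cavity <= self.icm_radius[1]:
            raise ValueError(
                "ring ranges cannot guarantee ZP > TE > cavity > ICM nesting: "
                f"min cavity radius {cavity:.1f} px <= max ICM radius {self.icm_radius[1]:.1f} px"
            )
        if self.zp_outer_radius[1] >= self.image_size / 2:
            raise ValueError("zp_outer_radius must fit inside the frame")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("zp_outer_radius", "zp_thickness", "te_thickness", "icm_radius"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _rng_for(config: PhantomConfig, sample_index: int) -> np.random.Generator:
    # One seed stream per sample index -> dataset is order-independent.
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(sample_index,)))


def generate_phantom(config: PhantomConfig, sample_index: int = 0) -> ImageSample:
    """Render one phantom image/mask pair, deterministic in (seed, index).

    The mask partitions the frame: BG outside the embryo, ZP outer annulus,
    TE annulus inside it, BL cavity, and a single 4-connected ICM blob
    touching the inner TE wall.
    """
    rng = _rng_for(config, sample_index)
    s = config.image_size
    cy, cx = (s - 1) / 2 + rng.uniform(-config.center_jitter, config.center_jitter, size=2)

    r_zp_out = rng.uniform(*config.zp_outer_radius)
    r_zp_in = r_zp_out - rng.uniform(*config.zp_thickness)
    r_te_in = r_zp_in - rng.uniform(*config.te_thickness)
    r_icm = rng.uniform(*config.icm_radius)

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    # Low-order angular wobble makes rings organically non-circular.
    amp = config.boundary_wobble * config.zp_thickness[0]
    def wobble() -> np.ndarray:
        a1, a2 = rng.uniform(-amp, amp, size=2)
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        return a1 * np.sin(theta + p1) + a2 * np.sin(2 * theta + p2)

    mask = np.full((s, s), BG, dtype=np.int64)
    mask[r <= r_zp_out + wobble()] = ZP
    mask[r <= r_zp_in + wobble()] = TE
    inner = r <= r_te_in + wobble()
    mask[inner] = BL

    # ICM: a disk whose centre sits inside the cavity but whose rim pokes
    # past the inner TE wall, clipped to the cavity -> guaranteed contact.
    phi = rng.uniform(0, 2 * np.pi)
    d_icm = max(r_te_in - 0.8 * r_icm, 0.0)
    icy, icx = cy + d_icm * np.sin(phi), cx + d_icm * np.cos(phi)
    icm_disk = np.hypot(yy - icy, xx - icx) <= r_icm
    mask[icm_disk & inner] = ICM

    gray = np.empty(5)
    for name, idx, _ in CLASS_MAP.entries:
        gray[idx] = config.class_gray_levels[name]
    image = gray[mask]

    if config.illumination_gradient > 0:
        ang = rng.uniform(0, 2 * np.pi)
        ramp = (np.cos(ang) * (xx - s / 2) + np.sin(ang) * (yy - s / 2)) / s
        image = image + config.illumination_gradient * ramp
    if config.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=config.blur_sigma)
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=image.shape)

    image = np.clip(image, 0.0, 1.0)
    return ImageSample(image=image, mask=mask, sample_id=f"phantom_{sample_index:05d}").validate()


def generate_dataset(
    config: PhantomConfig,
    n: int,
    out_dir: str | Path | None = None,
    train_fraction: float = 0.85,
) -> tuple[DatasetManifest, list[ImageSample]]:
    """Generate ``n`` phantoms, optionally writing PNGs + CSV manifest.

    Returns the manifest (with a deterministic train/test split) and the
    in-memory samples.  When ``out_dir`` is given, images are stored as 8-bit
    grayscale PNGs and masks as index PNGs, plus ``manifest.csv`` and the
    generator config as ``phantom_config.yaml``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    samples = [generate_phantom(config, i) for i in range(n)]
    ids = [smp.sample_id for smp in samples]
    if n >= 2:
        manifest = split_dataset(ids, train_fraction=train_fraction, seed=config.seed)
    else:
        manifest = DatasetManifest(
            records=[ManifestRecord(ids[0], f"{ids[0]}_image.png", f"{ids[0]}_mask.png", "train")],
            split_seed=config.seed,
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for smp, rec in zip(samples, manifest.records):
            write_image(smp.image, out / rec.image_path)
            write_mask(smp.mask, out / rec.mask_path, mode="index")
        manifest.write_csv(out / "manifest.csv")
        config.to_yaml(out / "phantom_config.yaml")
    return manifest, samples
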