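"""Synthetic T1-like tumor phantom generator.

Real nasopharyngeal-carcinoma slices are private, so this module emulates
their statistical structure for testing and training exercises: normalized
intensities in [0, 1], a smooth anatomical background (low-frequency Gaussian
random field plus pixel noise), and a single connected -- occasionally
multi-lobed -- hyperintense foreground region whose area fraction is drawn
log-uniformly across a wide range, reproducing the large scale variation of
tumor cross-sections that motivates a multi-scale architecture. Shapes are
randomly oriented ellipses perturbed by a low-order radial Fourier series
(tumors have no particular regular shape).

The generator is fully deterministic: a (config seed, pair index) pair maps
to an independent random stream, so datasets are bit-reproducible and any
pair can be regenerated in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .config import PhantomConfig

__all__ = [
    "SlicePair",
    "PhantomGenerationError",
    "generate_pair",
    "generate_dataset",
    "generate_arrays",
    "load_dataset",
]

MAX_ATTEMPTS = 50


class PhantomGenerationError(RuntimeError):
    """Rejection sampling failed; the area range is degenerate for the grid."""


@dataclass
class SlicePair:
    """One normalized slice and its binary ground-truth mask."""

    image: np.ndarray  # float32 in [0, 1]
    mask: np.ndarray   # uint8 in {0, 1}

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean())


def _pair_rng(config: PhantomConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, int(index)])


def _lobed_mask(rng: np.random.Generator, size: int, target_frac: float,
                n_lobes: int, jitter: float) -> np.ndarray:
    """Rasterise a union of perturbed, overlapping ellipses.

    The base radius is rescaled from the measured area a few times so the
    foreground fraction converges near its log-uniformly drawn target.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    r0 = size * np.sqrt(target_frac / (np.pi * max(n_lobes, 1) * 0.7))
    margin = min(0.35, max(0.12, 1.5 * r0 / size))
    c0 = rng.uniform(margin * size, (1 - margin) * size, size=2)
    centers = [c0]
    for _ in range(n_lobes - 1):
        ang = rng.uniform(0, 2 * np.pi)
        centers.append(centers[0] + 0.9 * r0 * np.array([np.sin(ang), np.cos(ang)]))
    lobes = []
    for c in centers:
        ecc = rng.uniform(0.7, 1.3)
        theta0 = rng.uniform(0, 2 * np.pi)
        scale = rng.uniform(0.75, 1.0)
        coeffs = [(k, rng.normal(0.0, jitter / k), rng.uniform(0, 2 * np.pi))
                  for k in (2, 3, 4)]
        lobes.append((c, ecc, theta0, scale, coeffs))

    def rasterize(radius: float) -> np.ndarray:
        mask = np.zeros((size, size), dtype=bool)
        for (c, ecc, theta0, scale, coeffs) in lobes:
            dy, dx = yy - c[0], xx - c[1]
            ry = (np.cos(theta0) * dy - np.sin(theta0) * dx) / ecc
            rx = (np.sin(theta0) * dy + np.cos(theta0) * dx) * ecc
            dist = np.hypot(ry, rx)
            ang = np.arctan2(ry, rx)
            boundary = np.ones_like(ang)
            for k, a_k, phi in coeffs:
                boundary += a_k * np.cos(k * ang + phi)
            mask |= dist <= radius * scale * np.maximum(boundary, 0.2)
        return mask

    radius = r0
    mask = rasterize(radius)
    for _ in range(6):
        frac = mask.mean()
        if frac == 0:
            radius *= 1.6
        else:
            err = frac / target_frac
            if 0.95 < err < 1.05:
                break
            radius *= np.sqrt(1.0 / err)
        mask = rasterize(radius)
    return mask.astype(np.uint8)


def generate_pair(config: PhantomConfig, index: int) -> SlicePair:
    """Generate the ``index``-th slice/mask pair of the configured dataset."""
    if index < 0 or index >= config.n_pairs:
        raise IndexError(f"index {index} outside [0, {config.n_pairs})")
    rng = _pair_rng(config, index)
    size = config.image_size
    lo, hi = config.tumor_area_range
    if hi >= 1.2 * lo:
        lo_acc, hi_acc = lo, hi  # wide range: enforce strict containment
    else:
        # narrow range: pixelisation makes exact containment unattainable;
        # allow roughly one ring of boundary pixels of slack
        slack = 2.0 * np.sqrt(np.pi / max(lo * size * size, 1.0))
        lo_acc, hi_acc = lo * (1 - slack), hi * (1 + slack)
    for _ in range(MAX_ATTEMPTS):
        target = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        n_lobes = int(rng.integers(config.n_lobes_range[0],
                                   config.n_lobes_range[1] + 1))
        mask = _lobed_mask(rng, size, target, n_lobes, config.boundary_jitter)
        frac = mask.mean()
        if frac > 0 and lo_acc <= frac <= hi_acc:
            break
    else:
        raise PhantomGenerationError(
            f"could not draw a mask with area fraction in [{lo}, {hi}] on a "
            f"{size}x{size} grid after {MAX_ATTEMPTS} attempts"
        )
    # smooth anatomical surrogate + white noise, then tumor hyperintensity
    field = ndimage.gaussian_filter(
        rng.standard_normal((size, size)), config.background_smoothness
    )
    sd = field.std()
    if sd > 0:
        field /= sd
    image = config.background_mean + config.background_amplitude * field
    fg_texture = ndimage.gaussian_filter(rng.standard_normal((size, size)), 2.0)
    fg_sd = fg_texture.std()
    if fg_sd > 0:
        fg_texture /= fg_sd
    fg = config.foreground_mean + config.foreground_sd * fg_texture
    image = np.where(mask > 0, fg, image)
    image = ndimage.gaussian_filter(image, 0.8)  # soften the lesion boundary
    image += rng.normal(0.0, config.noise_sd, size=(size, size))
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SlicePair(image=image, mask=mask)


def generate_arrays(config: PhantomConfig):
    """All pairs as stacked arrays: images (n, H, W), masks (n, H, W)."""
    images = np.empty((config.n_pairs, config.image_size, config.image_size),
                      dtype=np.float32)
    masks = np.empty_like(images, dtype=np.uint8)
    for i in range(config.n_pairs):
        pair = generate_pair(config, i)
        images[i] = pair.image
        masks[i] = pair.mask
    return images, masks


def _write_png16(path: Path, image: np.ndarray) -> None:
    arr = np.round(np.clip(image, 0, 1) * 65535).astype(np.uint16)
    Image.fromarray(arr).save(path)


def _write_mask_png(path: Path, mask: np.ndarray) -> None:
    Image.fromarray((mask > 0).astype(np.uint8) * 255, mode="L").save(path)


def generate_dataset(config: PhantomConfig, out_dir) -> pd.DataFrame:
    """Write ``n_pairs`` image/mask PNGs plus a CSV manifest.

    Images are 16-bit grayscale PNG; masks are 8-bit {0, 255}. The manifest
    lists file names, the per-pair seed, and the foreground fraction.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    rows = []
    for i in range(config.n_pairs):
        pair = generate_pair(config, i)
        img_name = f"img_{i:04d}.png"
        mask_name = f"mask_{i:04d}.png"
        try:
            _write_png16(out_dir / img_name, pair.image)
            _write_mask_png(out_dir / mask_name, pair.mask)
        except OSError as exc:
            raise OSError(f"failed writing {out_dir / img_name}: {exc}") from exc
        rows.append({
            "file_image": img_name,
            "file_mask": mask_name,
            "seed": f"{config.seed}:{i}",
            "fg_fraction": pair.foreground_fraction,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(data_dir):
    """Read a generated dataset back as (images, masks) float/uint8 stacks."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    images, masks = [], []
    for _, row in manifest.iterrows():
        img = np.asarray(Image.open(data_dir / row["file_image"]), dtype=np.float32)
        images.append(img / 65535.0)
        mask = np.asarray(Image.open(data_dir / row["file_mask"]))
        masks.append((mask > 127).astype(np.uint8))
    return np.stack(images), np.stack(masks)


def dataset_checksum(out_dir) -> str:
    """SHA-256 over all PNG bytes and the manifest (reproducibility checks)."""
    h = hashlib.sha256()
    for path in sorted(Path(out_dir).glob("*.png")) + [Path(out_dir) / "manifest.csv"]:
        h.update(path.name.encode())
        h.update(path.read_bytes())
    return h.hexdigest()
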