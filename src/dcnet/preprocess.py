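"""Preprocessing: normalization, resampling, reorientation, augmentation.

The pipeline is 2D: volumes are reoriented to RAS+, min-max normalized to
[0, 1], split into transverse slices, and each slice resampled to a fixed
grid (256x256 at 1 mm) with cubic splines for images and nearest-neighbour
for masks. Augmentation applies the same random rotation (within +/-10
degrees), flip, and integer translation to an image and its mask; the mask
is resampled nearest-neighbour so it stays strictly binary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .config import AugmentConfig
from .phantom import SlicePair

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "normalize",
    "normalize_array",
    "resample_slice",
    "reorient_ras",
    "augment",
    "volume_to_slices",
]

_VALID_AXES = {"R", "L", "A", "P", "S", "I"}


@dataclass
class Volume:
    """A 3D scalar volume with voxel spacing (mm) and an anatomical
    orientation code such as ``RAS`` or ``LPS``."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        code = (self.orientation or "").upper().replace("+", "")
        if len(code) != 3 or set(code) - _VALID_AXES or (
            len({a.translate(str.maketrans("LPI", "RAS")) for a in code}) != 3
        ):
            raise ValueError(f"invalid orientation code {self.orientation!r}")
        self.orientation = code

    @classmethod
    def from_nifti(cls, path) -> "Volume":
        img = nib.load(str(path))
        axcodes = nib.aff2axcodes(img.affine)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.get_fdata()), spacing, "".join(axcodes))

    def to_nifti(self, path) -> None:
        aff = np.diag(list(self.spacing) + [1.0])
        ornt = nib.orientations.axcodes2ornt(tuple(self.orientation))
        # build an affine whose axis codes match ``orientation``
        perm = nib.orientations.inv_ornt_aff(ornt, self.voxels.shape)
        nib.Nifti1Image(np.asarray(self.voxels, dtype=np.float32),
                        aff @ perm).to_filename(str(path))


def normalize_array(values: np.ndarray) -> np.ndarray:
    """Min-max map to [0, 1]; a constant input maps to all zeros (logged)."""
    values = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite voxel values")
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        logger.warning("constant-valued input: degenerate contrast, output is 0")
        return np.zeros_like(values, dtype=np.float32)
    return ((values - vmin) / (vmax - vmin)).astype(np.float32)


def normalize(volume: Volume) -> Volume:
    """Min-max normalize a volume's voxel values into [0, 1]."""
    return Volume(normalize_array(volume.voxels), volume.spacing,
                  volume.orientation)


def resample_slice(image: np.ndarray, in_spacing: float = 1.0,
                   target_size: int = 256, target_spacing: float = 1.0,
                   order: int = 3) -> np.ndarray:
    """Resample a 2D slice onto a ``target_size`` grid at ``target_spacing``.

    Cubic splines (order 3) for images; ``order=0`` for masks so no new
    label values appear. Output pixel (i, j) samples the input at physical
    position (i, j) * target_spacing (corner-aligned grids).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("resample_slice expects a 2D array")
    if in_spacing <= 0 or target_spacing <= 0:
        raise ValueError("spacings must be positive")
    if image.shape == (target_size, target_size) and in_spacing == target_spacing:
        return image.copy()
    scale = target_spacing / in_spacing
    coords = np.arange(target_size) * scale
    grid = np.meshgrid(coords, coords, indexing="ij")
    out = ndimage.map_coordinates(
        image.astype(np.float64), np.stack(grid), order=order, mode="nearest"
    )
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite values after interpolation (corrupt input?)")
    return out.astype(image.dtype) if order == 0 else out


def reorient_ras(volume: Volume) -> Volume:
    """Permute/flip axes so the volume is in RAS+ orientation."""
    if not volume.orientation:
        raise ValueError("missing orientation metadata; refusing to guess")
    src = nib.orientations.axcodes2ornt(tuple(volume.orientation))
    dst = nib.orientations.axcodes2ornt(("R", "A", "S"))
    transform = nib.orientations.ornt_transform(src, dst)
    voxels = nib.orientations.apply_orientation(volume.voxels, transform)
    perm = transform[:, 0].astype(int)
    spacing = tuple(volume.spacing[p] for p in perm)
    return Volume(voxels, spacing, "RAS")


def volume_to_slices(volume: Volume, target_size: int = 256) -> list[np.ndarray]:
    """Transverse (axial) slices of a RAS+ volume, resampled and normalized."""
    vol = reorient_ras(volume)
    vol = normalize(vol)
    slices = []
    for k in range(vol.voxels.shape[2]):
        sl = resample_slice(vol.voxels[:, :, k], in_spacing=vol.spacing[0],
                            target_size=target_size)
        slices.append(np.clip(sl, 0.0, 1.0))
    return slices


def augment(pair: SlicePair, rng: np.random.Generator,
            params: AugmentConfig | None = None) -> SlicePair:
    """Apply one random rotation/flip/translation draw to a slice pair.

    Each transform fires independently with its configured probability; the
    identical geometric transform is applied to image (linear interpolation)
    and mask (nearest-neighbour, re-binarised).
    """
    params = params if params is not None else AugmentConfig()
    image = np.asarray(pair.image, dtype=np.float32)
    mask = np.asarray(pair.mask)
    if rng.random() < params.p_rotate:
        angle = rng.uniform(-params.max_angle_deg, params.max_angle_deg)
        image = ndimage.rotate(image, angle, reshape=False, order=1,
                               mode="constant", cval=0.0)
        mask = ndimage.rotate(mask, angle, reshape=False, order=0,
                              mode="constant", cval=0)
    if rng.random() < params.p_flip:
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    if rng.random() < params.p_translate:
        shift = rng.integers(-params.max_shift_px, params.max_shift_px + 1, size=2)
        image = ndimage.shift(image, shift, order=0, mode="constant", cval=0.0)
        mask = ndimage.shift(mask, shift, order=0, mode="constant", cval=0)
    image = np.clip(image, 0.0, 1.0)
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    return SlicePair(image=np.ascontiguousarray(image),
                     mask=np.ascontiguousarray(mask))
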