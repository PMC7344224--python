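"""Training-time geometric augmentation (plus optional gamma contrast).

The composition order is fixed: flips -> rotation -> scaling -> random crop,
with the crop always last so every training sample leaves the pipeline at the
network's fixed input size. Random cropping doubles as random shifting: the
crop window is drawn uniformly over all positions where it fits inside the
(zero-padded, if necessary) transformed image. Images are interpolated
bilinearly and label maps nearest-neighbour, mirroring the resampling kernels
of the normalization stage. Each transform is individually toggleable, which
is what the augmentation ablation switches off row by row.

Gamma contrast augmentation (x -> x^gamma on intensities rescaled to [0, 1])
is implemented but disabled by default: it brought only minor gains and is
not part of the standard pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .types import ValidationError


@dataclass
class AugmentConfig:
    """Toggles and ranges of the stochastic training transforms.

    Flips are horizontal and vertical, each applied independently with
    probability 0.5. Rotation angles are drawn uniformly from
    [-30, +30] degrees and scale factors from [0.7, 1.4].
    """

    flip_enabled: bool = True
    rotation_enabled: bool = True
    rotation_range_deg: Tuple[float, float] = (-30.0, 30.0)
    scale_enabled: bool = True
    scale_range: Tuple[float, float] = (0.7, 1.4)
    crop_shift_enabled: bool = True
    gamma_enabled: bool = False
    gamma_range: Tuple[float, float] = (0.7, 1.5)
    flip_probability: float = 0.5

    def __post_init__(self) -> None:
        for lo, hi in (self.rotation_range_deg, self.scale_range, self.gamma_range):
            if not lo < hi:
                raise ValidationError(f"range must be ordered lo < hi, got ({lo}, {hi})")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        """All transforms off: the pipeline reduces to the deterministic path."""
        return cls(flip_enabled=False, rotation_enabled=False, scale_enabled=False,
                   crop_shift_enabled=False, gamma_enabled=False)


@dataclass
class AugmentationDraw:
    """The sampled parameters of one augmentation event."""

    flip_h: bool = False
    flip_v: bool = False
    angle_deg: float = 0.0
    scale: float = 1.0
    crop_uv: Tuple[float, float] = (0.5, 0.5)  # fractional crop position in [0,1]^2
    gamma: Optional[float] = None

    def is_identity(self) -> bool:
        return (not self.flip_h and not self.flip_v and self.angle_deg == 0.0
                and self.scale == 1.0 and self.crop_uv == (0.5, 0.5)
                and self.gamma is None)


def draw_augmentation(config: AugmentConfig, rng: np.random.Generator) -> AugmentationDraw:
    """Sample one augmentation event; disabled transforms yield identity.

    The crop position is drawn as a fractional (u, v) in [0, 1]^2 and mapped
    to integer offsets once the transformed image size is known, so one draw
    is valid for any input size. A centred crop is (0.5, 0.5).
    """
    draw = AugmentationDraw()
    if config.flip_enabled:
        draw.flip_h = bool(rng.random() < config.flip_probability)
        draw.flip_v = bool(rng.random() < config.flip_probability)
    if config.rotation_enabled:
        draw.angle_deg = float(rng.uniform(*config.rotation_range_deg))
    if config.scale_enabled:
        draw.scale = float(rng.uniform(*config.scale_range))
    if config.crop_shift_enabled:
        draw.crop_uv = (float(rng.random()), float(rng.random()))
    if config.gamma_enabled:
        draw.gamma = float(rng.uniform(*config.gamma_range))
    return draw


def gamma_contrast(image_slice: np.ndarray, gamma: float) -> np.ndarray:
    """Monotone contrast map x -> x^gamma on intensities rescaled to [0, 1].

    Applied to raw (pre-normalization) intensities; preserves pixel rank
    order for any gamma > 0. The output is returned on the original intensity
    scale.
    """
    if gamma <= 0:
        raise ValidationError(f"gamma must be > 0, got {gamma}")
    x = np.asarray(image_slice, dtype=np.float32)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return x.copy()
    unit = (x - lo) / (hi - lo)
    return (unit ** np.float32(gamma)) * (hi - lo) + lo


def _rotate(arr: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    return ndimage.rotate(arr, angle_deg, reshape=False, order=order,
                          mode="constant", cval=0.0, prefilter=False)


def _zoom(arr: np.ndarray, scale: float, order: int) -> np.ndarray:
    out = ndimage.zoom(arr, scale, order=order, mode="grid-constant", cval=0.0,
                       prefilter=False, grid_mode=True)
    return out


def _crop_at(arr: np.ndarray, crop_size: Tuple[int, int],
             uv: Tuple[float, float]) -> np.ndarray:
    h, w = crop_size
    ih, iw = arr.shape
    if ih < h or iw < w:
        pb = (max(0, (h - ih) // 2), max(0, (w - iw) // 2))
        pa = (max(0, h - ih - pb[0]), max(0, w - iw - pb[1]))
        arr = np.pad(arr, ((pb[0], pa[0]), (pb[1], pa[1])))
        ih, iw = arr.shape
    def offset(u: float, diff: int) -> int:
        if u == 0.5:  # identity draw: exactly the deterministic central crop
            return diff // 2
        return min(int(u * (diff + 1)), diff)  # uniform over all fits
    dy = offset(uv[0], ih - h)
    dx = offset(uv[1], iw - w)
    return arr[dy:dy + h, dx:dx + w]


def apply_augmentation(image_slice: np.ndarray, label_slice: Optional[np.ndarray],
                       draw: AugmentationDraw,
                       crop_size: Tuple[int, int]):
    """Apply one drawn augmentation to an image slice and its label slice.

    Both receive the identical geometric transform (flips -> rotation ->
    scale -> crop); the image is interpolated bilinearly and the label
    nearest-neighbour, so label values stay in the class alphabet. Outputs
    have exactly ``crop_size`` shape.
    """
    img = np.asarray(image_slice, dtype=np.float32)
    lab = None if label_slice is None else np.asarray(label_slice)
    if lab is not None and lab.shape != img.shape:
        raise ValidationError(f"image {img.shape} and label {lab.shape} grids differ")
    if draw.gamma is not None:
        img = gamma_contrast(img, draw.gamma)
    if draw.flip_h:
        img = img[:, ::-1]
        lab = None if lab is None else lab[:, ::-1]
    if draw.flip_v:
        img = img[::-1, :]
        lab = None if lab is None else lab[::-1, :]
    if draw.angle_deg != 0.0:
        img = _rotate(img, draw.angle_deg, order=1)
        lab = None if lab is None else _rotate(lab, draw.angle_deg, order=0)
    if draw.scale != 1.0:
        img = _zoom(img, draw.scale, order=1)
        lab = None if lab is None else _zoom(lab, draw.scale, order=0)
    img = np.ascontiguousarray(_crop_at(img, crop_size, draw.crop_uv))
    if lab is not None:
        lab = np.ascontiguousarray(_crop_at(lab, crop_size, draw.crop_uv))
    return img, lab
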