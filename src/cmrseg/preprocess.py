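"""Data normalization applied identically at train and test time.

The pipeline per frame: (1) in-plane resampling to a standard pixel spacing
of 1.25 x 1.25 mm (bilinear for images, nearest-neighbour for labels; slice
count and slice thickness are never changed), (2) central crop / symmetric
zero-pad to a fixed in-plane size, (3) per-slice intensity standardization to
zero mean, unit variance. The exact inverse — uncrop, bilinear rescale of the
class scores to the original grid, then per-pixel argmax — restores network
outputs to the scanner grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from skimage.transform import resize

from .types import GeometryRecord, LabelMap, ValidationError, VolumeImage


@dataclass
class PreprocessConfig:
    """Normalization settings shared by training and testing.

    target_spacing_mm : in-plane (ty, tx) the images are resampled to.
    crop_size : fixed (H, W) fed to the network; must be even (and, for the
        default 5-level U-Net, divisible by 16).
    resample_enabled : ablation toggle for the resampling step.
    """

    target_spacing_mm: Tuple[float, float] = (1.25, 1.25)
    crop_size: Tuple[int, int] = (256, 256)
    resample_enabled: bool = True

    def __post_init__(self) -> None:
        ty, tx = self.target_spacing_mm
        if ty <= 0 or tx <= 0:
            raise ValidationError(f"target spacing must be > 0, got {self.target_spacing_mm}")
        h, w = self.crop_size
        if h <= 0 or w <= 0 or h % 2 or w % 2:
            raise ValidationError(f"crop_size must be positive and even, got {self.crop_size}")


def _round_half_away(x: float) -> int:
    """Round half away from zero (0.5 -> 1), platform-independent."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def resampled_shape(shape_yx: Tuple[int, int], spacing_yx: Tuple[float, float],
                    target_yx: Tuple[float, float]) -> Tuple[int, int]:
    """Output in-plane shape: round(shape * spacing / target), half away from zero."""
    return tuple(_round_half_away(n * s / t)
                 for n, s, t in zip(shape_yx, spacing_yx, target_yx))


def _resize_stack(stack: np.ndarray, out_yx: Tuple[int, int], order: int) -> np.ndarray:
    out = np.empty((stack.shape[0], *out_yx), dtype=np.float32)
    for z in range(stack.shape[0]):
        out[z] = resize(stack[z].astype(np.float32), out_yx, order=order,
                        mode="edge", anti_aliasing=False, preserve_range=True)
    return out


def resample_inplane(
    obj: Union[VolumeImage, LabelMap],
    target_spacing: Tuple[float, float] = (1.25, 1.25),
) -> Union[VolumeImage, LabelMap]:
    """Resample in-plane to ``target_spacing``; slice axis untouched.

    Images are interpolated bilinearly, label maps nearest-neighbour. When the
    in-plane spacing already equals the target the input grid is returned
    unchanged (up to dtype).
    """
    ty, tx = (float(t) for t in target_spacing)
    if ty <= 0 or tx <= 0:
        raise ValidationError(f"target spacing must be > 0, got {target_spacing}")
    sz, sy, sx = obj.spacing
    arr = obj.labels if isinstance(obj, LabelMap) else obj.voxels
    out_yx = resampled_shape(arr.shape[1:], (sy, sx), (ty, tx))
    new_spacing = (sz, ty, tx)
    if out_yx == arr.shape[1:] and (sy, sx) == (ty, tx):
        resampled = arr.copy()
    elif isinstance(obj, LabelMap):
        resampled = _resize_stack(arr, out_yx, order=0).astype(np.uint8)
    else:
        resampled = _resize_stack(arr, out_yx, order=1)
    if isinstance(obj, LabelMap):
        return LabelMap(resampled, new_spacing)
    return VolumeImage(resampled, new_spacing)


def crop_geometry(in_yx: Tuple[int, int], crop_size: Tuple[int, int]):
    """Per-axis (offset, pad_before, pad_after) of the central crop/pad."""
    offs, pb, pa = [], [], []
    for n, c in zip(in_yx, crop_size):
        if n >= c:
            offs.append((n - c) // 2)
            pb.append(0)
            pa.append(0)
        else:
            offs.append(0)
            pb.append((c - n) // 2)
            pa.append(c - n - (c - n) // 2)
    return tuple(offs), tuple(pb), tuple(pa)


def center_crop_or_pad(grid: np.ndarray, crop_size: Tuple[int, int],
                       pad_value: float = 0.0):
    """Central crop (larger axes) / symmetric zero-pad (smaller axes) to crop_size.

    Accepts a 2D slice or a (Z, Y, X) stack; returns the fixed-size grid and
    the (offsets, pad_before, pad_after) tuple needed for exact inversion.
    """
    squeeze = grid.ndim == 2
    stack = grid[np.newaxis] if squeeze else grid
    offs, pb, pa = crop_geometry(stack.shape[1:], crop_size)
    h, w = crop_size
    win = stack[:, offs[0]:offs[0] + min(stack.shape[1], h),
                offs[1]:offs[1] + min(stack.shape[2], w)]
    if any(pb) or any(pa):
        win = np.pad(win, ((0, 0), (pb[0], pa[0]), (pb[1], pa[1])),
                     mode="constant", constant_values=pad_value)
    out = win[0] if squeeze else win
    return out, (offs, pb, pa)


def uncrop(grid: np.ndarray, resampled_yx: Tuple[int, int],
           offs: Tuple[int, int], pb: Tuple[int, int], pa: Tuple[int, int],
           fill: float = 0.0) -> np.ndarray:
    """Exact inverse of :func:`center_crop_or_pad` on the recorded geometry."""
    squeeze = grid.ndim == 2
    stack = grid[np.newaxis] if squeeze else grid
    h, w = stack.shape[1] - pb[0] - pa[0], stack.shape[2] - pb[1] - pa[1]
    inner = stack[:, pb[0]:pb[0] + h, pb[1]:pb[1] + w]
    out = np.full((stack.shape[0], *resampled_yx), fill, dtype=stack.dtype)
    out[:, offs[0]:offs[0] + h, offs[1]:offs[1] + w] = inner
    return out[0] if squeeze else out


def normalize_intensity(slice2d: np.ndarray) -> np.ndarray:
    """Standardize one cropped 2D slice to mean 0, s.d. 1; a constant slice
    (e.g. all-zero padding) maps to zeros."""
    x = np.asarray(slice2d, dtype=np.float32)
    mu = float(x.mean())
    sd = float(x.std())
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - mu) / sd


def preprocess_frame(image: VolumeImage, config: PreprocessConfig,
                     label: LabelMap | None = None):
    """Full deterministic test-time path for one frame.

    Returns ``(slices, geometry, label_slices)`` where ``slices`` is a
    (Z, H, W) float32 stack of normalized slices, ``geometry`` the complete
    :class:`GeometryRecord`, and ``label_slices`` the identically cropped
    label stack (or None). The label, when given, shares the image's grid.
    """
    original_shape = image.shape
    original_spacing = image.spacing
    if config.resample_enabled:
        image_r = resample_inplane(image, config.target_spacing_mm)
        label_r = resample_inplane(label, config.target_spacing_mm) if label else None
    else:
        image_r, label_r = image, label
    resampled_yx = image_r.shape[1:]
    cropped, (offs, pb, pa) = center_crop_or_pad(image_r.voxels, config.crop_size)
    slices = np.stack([normalize_intensity(s) for s in cropped])
    geometry = GeometryRecord(
        original_shape=original_shape,
        original_spacing=original_spacing,
        resampled_shape=tuple(resampled_yx),
        target_size=tuple(config.crop_size),
        crop_offsets=offs, pad_before=pb,
        resampled=config.resample_enabled,
    )
    label_slices = None
    if label_r is not None:
        label_slices, _ = center_crop_or_pad(label_r.labels, config.crop_size)
        label_slices = label_slices.astype(np.uint8)
    return slices, geometry, label_slices


def restore_prediction(per_class_scores: np.ndarray,
                       geometry: GeometryRecord) -> LabelMap:
    """Map per-class network scores back onto the original scanner grid.

    ``per_class_scores`` is (Z, C, H, W) (or (C, H, W) for a single slice) on
    the network grid. Scores are uncropped/unpadded to the resampled grid,
    bilinearly rescaled in-plane to the original grid, and only then reduced
    by per-pixel argmax — ties resolve to the lowest class index.
    """
    if not isinstance(geometry, GeometryRecord) or not geometry.is_complete():
        raise ValidationError("restore_prediction requires a complete GeometryRecord")
    scores = np.asarray(per_class_scores, dtype=np.float32)
    if scores.ndim == 3:
        scores = scores[np.newaxis]
    z, c, h, w = scores.shape
    if (h, w) != tuple(geometry.target_size):
        raise ValidationError(
            f"score grid {(h, w)} != geometry target_size {geometry.target_size}")
    offs = geometry.crop_offsets
    # pad-after is implied by the recorded shapes
    _, pb2, pa2 = crop_geometry(geometry.resampled_shape, geometry.target_size)
    out_yx = geometry.original_shape[1:]
    restored = np.empty((z, c, *out_yx), dtype=np.float32)
    for zi in range(z):
        on_resampled = uncrop(scores[zi], geometry.resampled_shape, offs, pb2, pa2)
        if tuple(out_yx) == tuple(geometry.resampled_shape):
            restored[zi] = on_resampled
        else:
            for ci in range(c):
                restored[zi, ci] = resize(on_resampled[ci], out_yx, order=1,
                                          mode="edge", anti_aliasing=False,
                                          preserve_range=True)
    labels = np.argmax(restored, axis=1).astype(np.uint8)  # ties -> lowest class
    return LabelMap(labels, geometry.original_spacing)
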