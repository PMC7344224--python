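"""Core data types for short-axis cine CMR segmentation.

Internal index order is fixed as (z, y, x): slice, row, column. NIfTI files
store axes in (x, y, z) order on disk; the adaptation happens once, at the
I/O boundary (:mod:`cmrseg.io`), so every in-memory array in this package
follows the one convention.

Class codes for label maps: 0 background, 1 LV blood pool, 2 LV myocardium,
3 RV blood pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

#: Segmentation class codes.
BG, LV, MYO, RV = 0, 1, 2, 3

#: Names of the three foreground structures, keyed by class code.
STRUCTURES = {LV: "LV", MYO: "MYO", RV: "RV"}

#: The full label alphabet.
CLASSES = (BG, LV, MYO, RV)


class ValidationError(ValueError):
    """Raised when a domain invariant is violated (bad labels, spacings, shapes)."""


def _check_spacing(spacing) -> Tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValidationError(f"spacing must have 3 entries (sz, sy, sx), got {spacing}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValidationError(f"spacings must be finite and > 0, got {spacing}")
    return spacing


@dataclass
class VolumeImage:
    """A 3D stack of scalar intensities with physical voxel spacing.

    Parameters
    ----------
    voxels
        Array of shape (Z, Y, X), finite floats.
    spacing
        (sz, sy, sx) in mm per voxel, all > 0. sz is the slice thickness
        (centre-to-centre), sy/sx the in-plane pixel spacing.
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValidationError(f"voxels must be rank-3, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("image intensities contain NaN/Inf")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    def voxel_volume_mm3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx


@dataclass
class LabelMap:
    """An integer class map on the same grid as its paired :class:`VolumeImage`."""

    labels: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValidationError(f"labels must be rank-3, got shape {labels.shape}")
        bad = np.setdiff1d(np.unique(labels), np.array(CLASSES))
        if bad.size:
            raise ValidationError(f"label values outside {set(CLASSES)}: {bad.tolist()}")
        self.labels = labels.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    def mask(self, cls: int) -> np.ndarray:
        return self.labels == cls


@dataclass
class SubjectStudy:
    """Paired ED and ES frames of one subject, with optional reference labels.

    ``label_availability`` records which structures carry reference labels in
    which frame, supporting partially-labelled cohorts (e.g. LV in ED+ES but
    myocardium in ED only, no RV). Keys are ('ED'|'ES', class code) and a
    missing key means unavailable; fully-labelled studies may leave it empty
    and use :meth:`available`.
    """

    subject_id: str
    ed_image: VolumeImage
    es_image: VolumeImage
    ed_label: Optional[LabelMap] = None
    es_label: Optional[LabelMap] = None
    label_availability: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for frame, img, lab in (("ED", self.ed_image, self.ed_label),
                                ("ES", self.es_image, self.es_label)):
            if lab is not None and lab.shape != img.shape:
                raise ValidationError(
                    f"{frame} label shape {lab.shape} != image shape {img.shape} "
                    f"for subject {self.subject_id}")

    def frames(self):
        yield "ED", self.ed_image, self.ed_label
        yield "ES", self.es_image, self.es_label

    def available(self, frame: str, cls: int) -> bool:
        """Whether structure `cls` has a reference label in `frame`."""
        lab = self.ed_label if frame == "ED" else self.es_label
        if lab is None:
            return False
        if self.label_availability:
            return self.label_availability.get((frame, cls), False)
        return True


@dataclass
class GeometryRecord:
    """Invertible record of the preprocessing geometry applied to one frame.

    Stores everything needed to map a network output on the fixed-size grid
    back onto the original scanner grid: the original shape/spacing, the
    in-plane shape after resampling, and the signed crop offsets / pad amounts
    of the central crop. Applying the inverse to a (target_size) grid recovers
    original_shape exactly by construction.
    """

    original_shape: Tuple[int, int, int]
    original_spacing: Tuple[float, float, float]
    resampled_shape: Tuple[int, int]          # in-plane (Y', X') after resampling
    target_size: Tuple[int, int]              # (H, W) fed to the network
    crop_offsets: Tuple[int, int] = (0, 0)    # top-left of crop window in resampled grid
    pad_before: Tuple[int, int] = (0, 0)      # zero-padding added before the window
    resampled: bool = True

    def is_complete(self) -> bool:
        return (len(self.original_shape) == 3 and len(self.resampled_shape) == 2
                and len(self.target_size) == 2)
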