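"""NIfTI I/O for cine CMR frames and label maps.

One file holds one 3D volume (a single cardiac frame). On disk NIfTI axes are
(x, y, z); in memory this package uses (z, y, x), so arrays are transposed at
this boundary. Spacing is taken from the header ``pixdim`` (voxel
centre-to-centre, mm). Orientation codes are read but volumes are not
reoriented: pose variation is handled by the augmentation stage, not by
registration.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional, Tuple

import nibabel as nib
import numpy as np

from .types import CLASSES, LabelMap, SubjectStudy, ValidationError, VolumeImage


def _load_nifti(path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:
        data = data[..., np.newaxis]
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]  # (sx, sy, sz) on-disk order
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return np.ascontiguousarray(data.T), spacing  # -> (z, y, x)


def read_image(path) -> VolumeImage:
    """Read one frame as a :class:`VolumeImage` (intensities as float32)."""
    data, spacing = _load_nifti(path)
    data = np.asarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path}: non-finite intensities after load")
    return VolumeImage(data, spacing)


def read_labelmap(path) -> LabelMap:
    """Read one frame's label map; values must lie in {0,1,2,3}."""
    data, spacing = _load_nifti(path)
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-3):
        raise ValidationError(f"{path}: label volume has non-integer values")
    bad = np.setdiff1d(np.unique(rounded), np.array(CLASSES, dtype=rounded.dtype))
    if bad.size:
        raise ValidationError(f"{path}: label values outside {set(CLASSES)}: {bad.tolist()}")
    return LabelMap(rounded.astype(np.uint8), spacing)


def _affine_for(spacing: Tuple[float, float, float]) -> np.ndarray:
    sz, sy, sx = spacing
    return np.diag([sx, sy, sz, 1.0])


def write_image(image: VolumeImage, path) -> None:
    """Write a :class:`VolumeImage` as NIfTI, spacing preserved in the header."""
    data = np.asarray(image.voxels, dtype=np.float32).T  # (x, y, z) on disk
    nii = nib.Nifti1Image(data, _affine_for(image.spacing))
    nii.header.set_zooms((image.spacing[2], image.spacing[1], image.spacing[0]))
    nib.save(nii, os.fspath(path))


def write_labelmap(labelmap: LabelMap, path) -> None:
    """Write a :class:`LabelMap` as integer NIfTI, spacing preserved."""
    data = np.asarray(labelmap.labels, dtype=np.uint8).T
    nii = nib.Nifti1Image(data, _affine_for(labelmap.spacing))
    nii.header.set_zooms((labelmap.spacing[2], labelmap.spacing[1], labelmap.spacing[0]))
    nib.save(nii, os.fspath(path))


def read_study(
    image_paths: Mapping[str, object],
    label_paths: Optional[Mapping[str, object]] = None,
    subject_id: str = "subject",
    label_availability: Optional[Mapping[Tuple[str, int], bool]] = None,
) -> SubjectStudy:
    """Assemble a :class:`SubjectStudy` from per-frame NIfTI files.

    Parameters
    ----------
    image_paths
        Mapping with keys 'ED' and 'ES' to image files.
    label_paths
        Optional mapping with keys 'ED' and/or 'ES' to label files; a frame
        absent from the mapping has no reference labels.
    label_availability
        Optional per-(frame, class) availability flags for partially labelled
        studies; by default every class of a present label file counts as
        available.
    """
    for key in ("ED", "ES"):
        if key not in image_paths:
            raise ValidationError(f"image_paths must contain '{key}'")
    ed_image = read_image(image_paths["ED"])
    es_image = read_image(image_paths["ES"])
    ed_label = es_label = None
    if label_paths:
        if "ED" in label_paths:
            ed_label = read_labelmap(label_paths["ED"])
            if ed_label.shape != ed_image.shape:
                raise ValidationError(
                    f"ED label shape {ed_label.shape} does not match image shape {ed_image.shape}")
        if "ES" in label_paths:
            es_label = read_labelmap(label_paths["ES"])
            if es_label.shape != es_image.shape:
                raise ValidationError(
                    f"ES label shape {es_label.shape} does not match image shape {es_image.shape}")
    return SubjectStudy(
        subject_id=subject_id,
        ed_image=ed_image, es_image=es_image,
        ed_label=ed_label, es_label=es_label,
        label_availability=dict(label_availability or {}),
    )


def write_study(study: SubjectStudy, out_dir, prefix: Optional[str] = None) -> dict:
    """Write a study's frames (and any labels) to ``out_dir``; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    prefix = prefix or study.subject_id
    paths = {}
    for frame, img, lab in study.frames():
        ipath = os.path.join(out_dir, f"{prefix}_{frame}.nii.gz")
        write_image(img, ipath)
        paths[("image", frame)] = ipath
        if lab is not None:
            lpath = os.path.join(out_dir, f"{prefix}_{frame}_gt.nii.gz")
            write_labelmap(lab, lpath)
            paths[("label", frame)] = lpath
    return paths
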