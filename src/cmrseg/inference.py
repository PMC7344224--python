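"""Test-time path: normalize -> per-slice forward pass -> restore geometry.

Each frame is resampled and centrally cropped exactly as in training,
normalized per slice, passed through the network in evaluation mode (batch
norm on running statistics, dropout off), and the per-class scores are
mapped back onto the original scanner grid before the per-pixel argmax. No
test-time augmentation and no morphological post-processing are applied.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .preprocess import PreprocessConfig, preprocess_frame, restore_prediction
from .types import LabelMap, SubjectStudy, ValidationError, VolumeImage
from .unet import UNet


def segment_frame(network: UNet, image: VolumeImage,
                  config: PreprocessConfig) -> LabelMap:
    """Segment one 3D frame; the result shares the input's grid and spacing."""
    div = 2 ** (network.config.levels - 1)
    h, w = config.crop_size
    if h % div or w % div:
        raise ValidationError(
            f"crop_size {config.crop_size} is not divisible by the network's "
            f"required factor {div}")
    slices, geometry, _ = preprocess_frame(image, config)
    scores = network.predict_scores(slices)  # (Z, 4, H, W), eval mode
    return restore_prediction(scores, geometry)


def segment_study(network: UNet, study: SubjectStudy,
                  config: PreprocessConfig) -> Tuple[LabelMap, LabelMap]:
    """Segment both frames of a study -> (ED prediction, ES prediction)."""
    ed = segment_frame(network, study.ed_image, config)
    es = segment_frame(network, study.es_image, config)
    return ed, es
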