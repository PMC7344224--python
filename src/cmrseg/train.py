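"""Training loop: SGD on pixel-wise cross-entropy with step-decayed learning
rate and best-model selection by validation mean IoU.

Each epoch iterates over all 2D slices of all training frames in shuffled
order, drawing a fresh augmentation for every slice (online augmentation).
The same augmentation policy is applied to the validation slices — with a
per-epoch seed derived from the run seed, so the selection signal is
comparable across epochs — and the snapshot with the highest validation mean
IoU is returned (ties go to the earliest epoch, which acts as early
stopping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .augment import AugmentConfig, apply_augmentation, draw_augmentation
from .nn import SGD, cross_entropy
from .preprocess import (PreprocessConfig, center_crop_or_pad,
                         normalize_intensity, resample_inplane)
from .types import SubjectStudy, ValidationError
from .unet import UNet


@dataclass
class TrainConfig:
    """Optimization settings. Defaults are the full-scale protocol: batches
    of 20 2D slices, SGD at initial learning rate 0.001 halved every 50
    epochs, pixel-wise cross-entropy over the 4 classes."""

    batch_size: int = 20
    initial_lr: float = 0.001
    lr_decay_factor: float = 0.5
    lr_decay_every: int = 50
    momentum: float = 0.9
    epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.initial_lr <= 0:
            raise ValidationError("initial_lr must be > 0")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")

    def lr_at(self, epoch: int) -> float:
        """Learning rate in force during `epoch` (0-based)."""
        return self.initial_lr * self.lr_decay_factor ** (epoch // self.lr_decay_every)


@dataclass
class TrainingHistory:
    """Per-epoch loss and validation mean IoU, plus the selected best epoch."""

    train_loss: List[float] = field(default_factory=list)
    val_miou: List[float] = field(default_factory=list)
    best_epoch: int = -1
    best_miou: float = -1.0


def mean_iou(pred: np.ndarray, ref: np.ndarray, n_classes: int = 4) -> float:
    """Mean intersection-over-union between predicted and reference labels.

    Per-class IoU = |A n B| / |A u B| pooled over the whole batch; classes
    absent from both prediction and reference contribute nothing to the mean.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    ious = []
    for c in range(n_classes):
        a = pred == c
        b = ref == c
        union = int(np.logical_or(a, b).sum())
        if union == 0:
            continue
        ious.append(int(np.logical_and(a, b).sum()) / union)
    return float(np.mean(ious)) if ious else 1.0


def extract_slices(studies: List[SubjectStudy], preprocess: PreprocessConfig
                   ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Resample every labelled frame in-plane and return its (image slice,
    label slice) pairs at full (pre-crop) size. Frames without labels are
    skipped — supervision needs a reference."""
    pairs = []
    for study in studies:
        for _, image, label in study.frames():
            if label is None:
                continue
            if preprocess.resample_enabled:
                image = resample_inplane(image, preprocess.target_spacing_mm)
                label = resample_inplane(label, preprocess.target_spacing_mm)
            for z in range(image.shape[0]):
                pairs.append((image.voxels[z], label.labels[z]))
    return pairs


def _make_batch(pairs, indices, augment_cfg, crop_size, rng):
    imgs, labs = [], []
    for i in indices:
        draw = draw_augmentation(augment_cfg, rng)
        img, lab = apply_augmentation(pairs[i][0], pairs[i][1], draw, crop_size)
        imgs.append(normalize_intensity(img))
        labs.append(lab)
    return (np.stack(imgs)[:, np.newaxis],
            np.stack(labs).astype(np.int64))


def train_model(
    network: UNet,
    train_studies: List[SubjectStudy],
    val_studies: List[SubjectStudy],
    train_config: TrainConfig,
    preprocess_config: Optional[PreprocessConfig] = None,
    augment_config: Optional[AugmentConfig] = None,
    log=None,
) -> Tuple[UNet, TrainingHistory]:
    """Train `network` and return it loaded with its best-epoch weights.

    The run seed fans out to separate streams for shuffling, training
    augmentation, dropout and the per-epoch validation augmentation, so runs
    are bit-reproducible on CPU.
    """
    if not train_studies or not val_studies:
        raise ValidationError("training and validation sets must be non-empty")
    preprocess_config = preprocess_config or PreprocessConfig()
    augment_config = augment_config or AugmentConfig()

    train_pairs = extract_slices(train_studies, preprocess_config)
    val_pairs = extract_slices(val_studies, preprocess_config)
    if not train_pairs or not val_pairs:
        raise ValidationError("no labelled slices available for training/validation")

    root = np.random.SeedSequence(train_config.seed)
    shuffle_rng, aug_rng, drop_seed, val_seed0 = [
        np.random.default_rng(s) for s in root.spawn(4)]
    network.set_dropout_rng(drop_seed)

    # prior-probability initialization of the output head: softmax of the
    # initial logits matches the training label frequencies, which removes
    # the all-background cold-start on class-imbalanced data
    if "b" in network.head.params and not network.head.params["b"].any():
        counts = np.bincount(
            np.concatenate([lab.ravel() for _, lab in train_pairs]),
            minlength=network.config.out_classes).astype(np.float64)
        priors = np.maximum(counts, 1.0) / max(counts.sum(), 1.0)
        network.head.params["b"][...] = np.log(priors).astype(np.float32)
    val_epoch_seed = val_seed0.integers(0, 2**31 - 1)

    crop = preprocess_config.crop_size
    opt = SGD(network._all_layers(), lr=train_config.initial_lr,
              momentum=train_config.momentum)
    history = TrainingHistory()
    best_state = None

    n = len(train_pairs)
    for epoch in range(train_config.epochs):
        opt.lr = train_config.lr_at(epoch)
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            x, t = _make_batch(train_pairs, idx, augment_config, crop, aug_rng)
            logits = network.forward(x, train=True)
            loss, dlogits = cross_entropy(logits, t)
            if not np.isfinite(loss):
                raise ValidationError(
                    f"non-finite loss at epoch {epoch}, iteration {start // train_config.batch_size}")
            network.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))

        # validation mean IoU on identically-augmented validation slices;
        # fixed per-epoch seed keeps the signal comparable across epochs
        vrng = np.random.default_rng(val_epoch_seed)
        xv, tv = _make_batch(val_pairs, range(len(val_pairs)), augment_config,
                             crop, vrng)
        pred = np.concatenate(
            [network.forward(xv[i:i + 32], train=False).argmax(axis=1)
             for i in range(0, xv.shape[0], 32)])
        miou = mean_iou(pred, tv)
        history.val_miou.append(miou)
        if miou > history.best_miou:  # strict: ties keep the earliest epoch
            history.best_miou = miou
            history.best_epoch = epoch
            best_state = network.state_dict()
        if log is not None:
            log(f"epoch {epoch:3d} lr {opt.lr:.6f} "
                f"loss {history.train_loss[-1]:.4f} val_mIoU {miou:.4f}")

    network.load_state_dict(best_state)
    return network, history
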