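# cmrseg — generalizable short-axis cardiac MR segmentation

`cmrseg` is a training/testing pipeline for automatic multi-structure
segmentation of short-axis cine cardiovascular MR (CMR) images: the left
ventricular blood pool (LV), the LV myocardium (MYO) and the right
ventricular blood pool (RV), as integer classes {1, 2, 3} over background 0.

The problem it addresses is **cross-scanner / cross-site generalization**: a
convolutional network trained on images from one scanner tends to degrade on
images from other scanners and hospitals, which differ in pixel spacing,
contrast, noise, heart pose and patient population. The package implements a
pipeline whose answer to that problem is careful *data normalization* plus
*geometric data augmentation*, around a capacity-matched 2D U-Net:

- **Normalization** (train and test): in-plane resampling of every image to
  1.25 × 1.25 mm (bilinear for images, nearest-neighbour for labels; slice
  thickness untouched), central crop/zero-pad to a fixed grid, and per-slice
  intensity standardization to zero mean, unit variance.
- **Augmentation** (train only, on the fly): random horizontal/vertical
  flips (p = 0.5 each), rotation uniform in [−30°, +30°], scaling uniform in
  [0.7, 1.4], and random cropping (which doubles as random shifting) applied
  last so every sample leaves the pipeline at the network's input size.
  Every operation is individually toggleable, so the single-toggle ablation
  (remove resampling / rotation / flips / scaling one at a time) can be run
  as a study. Gamma contrast augmentation exists but is off by default.
- **Network**: a modified 2D U-Net — five encoder levels of
  [conv3×3–BN–ReLU ×2] with 2×2 max pooling, a decoder of four stages of
  [2× bilinear upsample → concatenate skip → dropout(0.2) →
  conv3×3–BN–ReLU ×2], and a 1×1 convolution to 4 logits. The width
  parameter `base_filters` *f* gives encoder channels (f, 2f, 4f, 8f, 8f)
  and decoder channels (4f, 2f, f, f): f = 64 has 13,382,464 convolution
  weights (~13.4 M), f = 16 has 836,560 (~0.84 M).
- **Training**: SGD on pixel-wise cross-entropy over batches of 2D slices
  (default 20), initial learning rate 0.001 halved every 50 epochs; model
  selection by the highest mean intersection-over-union on an augmented
  validation set (acts as early stopping).
- **Inference**: per-slice forward pass in evaluation mode, then the exact
  inverse of the normalization geometry — uncrop, bilinear rescale of the
  class scores to the original grid, argmax last — so predictions land on
  the scanner's native grid.
- **Evaluation**: per-structure 3D Dice `2|A∩B|/(|A|+|B|)`; the five
  clinical parameters LV-EDV, LV-ESV, RV-EDV, RV-ESV (mL) and LV mass
  (myocardial ED volume × 1.05 g/mL); Bland-Altman agreement (mean
  difference, sample s.d., limits of agreement MD ± 1.96 s.d.) with pairs
  whose per-pair mean falls outside 1.5 × IQR removed; Spearman rank
  correlation. Partially labelled cohorts (e.g. LV-only annotations) are
  respected throughout.

Because the clinical datasets this kind of pipeline is trained on are
access-restricted, the package ships a **synthetic short-axis phantom
generator**: multi-slice hearts built from analytic geometry (LV disk,
myocardial annulus, chiral RV crescent) with *closed-form* structure
volumes, ED/ES frame pairs with incompressible-wall contraction, unlabelled
background confuser tissue (chest-wall band, liver-like and random blobs
sharing the heart's intensities, anchored to the heart's pose so context is
orientation-informative), and two stock acquisition "domains" — a fixed single-scanner training domain and a
shifted multi-site test domain (pixel spacing 0.78–2.3 mm, poses ±45°,
mirrored hearts, contrast and noise shifts). Everything — training,
inference, clinical evaluation, the augmentation ablation — runs end-to-end
on one CPU with no data download.

## Worked example

```python
from cmrseg import (AugmentConfig, PreprocessConfig, TrainConfig, UNet,
                    UNetConfig, evaluate_dataset, generate_domain,
                    segment_study, train_model)

train_set = [s for s, _ in generate_domain("A", 8, seed=0)]
val_set   = [s for s, _ in generate_domain("A", 2, seed=1)]
test_set  = [s for s, _ in generate_domain("A", 4, seed=2)]

pre = PreprocessConfig(crop_size=(80, 80))           # 100 mm window at 1.25 mm
tc  = TrainConfig(batch_size=5, initial_lr=0.07, epochs=24, lr_decay_every=10,
                  seed=0)
net = UNet(UNetConfig(base_filters=8), seed=0)
net, history = train_model(net, train_set, val_set, tc, pre, AugmentConfig())

preds  = {s.subject_id: segment_study(net, s, pre) for s in test_set}
report = evaluate_dataset(preds, test_set)
print(report["dice_summary"])
```

Running `python examples/03_train_and_segment.py` (which is this example
with logging) prints the per-epoch progress and ends with

```
best epoch 18 (validation mean IoU 0.855)

per-structure 3D Dice on held-out subjects (mean over ED+ES frames):
                mean       std  count
structure
LV          0.976615  0.012565      8
MYO         0.913939  0.031837      8
RV          0.932979  0.038125      8

mean foreground Dice: 0.941
```

LV and myocardium are segmented accurately within minutes; the RV — whose
blood pool has the same intensity as the LV, so the network must learn shape
context against look-alike background tissue — is consistently the slowest
structure to converge (the test suite's 40-subject run reaches a mean
foreground Dice above 0.95). `examples/01_phantom_and_volumes.py` shows
the phantom's analytic-vs-voxel volume oracle, `02_network_architecture.py`
the architecture table, and `04_agreement_statistics.py` the Bland-Altman /
Spearman clinical agreement suite.

A thin CLI exposes the same pipeline for shell use:

```bash
cmrseg simulate --domain A --n 10 --seed 0 --out-dir data/train
cmrseg train --config cfg.yaml --train-dir data/train --val-dir data/val --out model.npz
cmrseg segment --checkpoint model.npz --in data/test/s0_ED.nii.gz --out-dir seg/
cmrseg evaluate --pred-dir seg/ --ref-dir data/test --out report
cmrseg describe --base-filters 64
```

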