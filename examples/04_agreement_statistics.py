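"""Clinical-parameter agreement between 'automatic' and manual segmentations.

Simulates an automatic reader by perturbing the phantom ground truth
(random boundary erosion/dilation), derives the five clinical parameters
(LV/RV end-diastolic and end-systolic volumes, LV mass) from both versions,
and runs the agreement suite: Bland-Altman mean difference, s.d., limits of
agreement (with extreme per-pair means removed by the 1.5 x IQR rule), and
Spearman rank correlation. With slice-wise contouring noise the bias stays
small and the cavity-volume rank correlations sit near 1; the myocardial
mass — a thin annulus, so boundary errors are a large volume fraction — is
visibly the noisiest parameter, as it is for human readers.
"""

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion

from cmrseg import LabelMap, PhantomConfig, evaluate_dataset, generate_study

rng = np.random.default_rng(0)
cohort, preds = [], {}
for i in range(24):
    # a cohort spanning small to dilated hearts, so between-subject variance
    # dominates the simulated reader noise
    cfg = PhantomConfig(r_base_mm=float(rng.uniform(14, 26)),
                        myo_thickness_mm=float(rng.uniform(6, 9)),
                        contraction=float(rng.uniform(0.6, 0.85)))
    study, _ = generate_study(cfg, seed=i, subject_id=f"s{i:02d}")
    cohort.append(study)
    noisy = []
    for lab in (study.ed_label, study.es_label):
        arr = lab.labels.copy()
        for cls in (1, 2, 3):
            m = arr == cls
            for z in range(arr.shape[0]):
                # slice-wise over/under-contouring, as human readers do
                op = binary_dilation if rng.random() < 0.5 else binary_erosion
                grown = op(m[z])
                arr[z][m[z] & ~grown] = 0
                arr[z][grown & (arr[z] == 0)] = cls
        noisy.append(LabelMap(arr, lab.spacing))
    preds[study.subject_id] = tuple(noisy)

report = evaluate_dataset(preds, cohort)
print("Bland-Altman + Spearman for the five clinical parameters "
      "(auto - manual):")
print(report["agreement"].round(3).to_string(index=False))
print("\nMD near 0 -> no systematic bias; LOA = MD +/- 1.96 SD bracket the "
      "disagreement;\nn_removed counts pairs dropped by the 1.5 x IQR rule on "
      "per-pair means.")
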