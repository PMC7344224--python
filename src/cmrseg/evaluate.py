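"""Evaluation: 3D Dice per structure, clinical parameters, agreement and
rank-correlation statistics.

Dice is the 3D overlap 2|A n B| / (|A| + |B|) computed per frame over the
whole stack and pooled over frames and subjects into a per-structure mean
(s.d.). Clinical parameters are the five standard ones: LV and RV
end-diastolic and end-systolic volumes (voxel count x voxel volume, mL) and
LV mass (myocardial ED volume x 1.05 g/mL tissue density). Automatic and
manual values are compared with Bland-Altman analysis — mean difference,
s.d. of differences (sample, n-1), limits of agreement MD +/- 1.96 s.d. —
after removing pairs whose per-pair mean falls outside [Q1 - 1.5 IQR,
Q3 + 1.5 IQR] of the mean distribution (extreme means would otherwise
inflate the s.d.), and with Spearman's rank correlation. Quartiles use
numpy's linear interpolation.

Partially labelled cohorts are respected throughout: a structure without a
reference label contributes no Dice entry and no parameter pair — never a
zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import LV, MYO, RV, STRUCTURES, LabelMap, SubjectStudy, ValidationError


# --------------------------------------------------------------------------
# overlap
# --------------------------------------------------------------------------

def dice_3d(auto: LabelMap, ref: LabelMap, structure_class: int) -> float:
    """3D Dice of one structure between two label maps on the same grid.

    Returns 1.0 when the structure is absent from both maps (perfect
    agreement on absence), 0.0 for disjoint non-empty masks.
    """
    if auto.shape != ref.shape:
        raise ValidationError(f"grid mismatch: {auto.shape} vs {ref.shape}")
    a = auto.labels == structure_class
    b = ref.labels == structure_class
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


# --------------------------------------------------------------------------
# clinical parameters
# --------------------------------------------------------------------------

MYO_DENSITY_G_PER_ML = 1.05

CLINICAL_PARAMS = ("LV_EDV", "LV_ESV", "LVM", "RV_EDV", "RV_ESV")


@dataclass
class ClinicalParams:
    """The five clinical parameters; a field is None when the structure has
    no reference (or predicted counterpart is not requested)."""

    LV_EDV: Optional[float] = None   # mL
    LV_ESV: Optional[float] = None   # mL
    LVM: Optional[float] = None      # g
    RV_EDV: Optional[float] = None   # mL
    RV_ESV: Optional[float] = None   # mL

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {k: getattr(self, k) for k in CLINICAL_PARAMS}


def structure_volume_ml(label: LabelMap, structure_class: int) -> float:
    """Voxel count times voxel volume, in mL."""
    sz, sy, sx = label.spacing
    return float((label.labels == structure_class).sum()) * sz * sy * sx / 1000.0


def clinical_params(ed_label: Optional[LabelMap], es_label: Optional[LabelMap],
                    availability=None) -> ClinicalParams:
    """Derive the five parameters from ED/ES label maps.

    `availability`, when given, is a callable (frame, class) -> bool marking
    which structures actually carry labels; unavailable ones yield None.
    """
    def avail(frame: str, cls: int) -> bool:
        lab = ed_label if frame == "ED" else es_label
        if lab is None:
            return False
        if availability is not None:
            return availability(frame, cls)
        return True

    out = ClinicalParams()
    if avail("ED", LV):
        out.LV_EDV = structure_volume_ml(ed_label, LV)
    if avail("ES", LV):
        out.LV_ESV = structure_volume_ml(es_label, LV)
    if avail("ED", MYO):
        out.LVM = structure_volume_ml(ed_label, MYO) * MYO_DENSITY_G_PER_ML
    if avail("ED", RV):
        out.RV_EDV = structure_volume_ml(ed_label, RV)
    if avail("ES", RV):
        out.RV_ESV = structure_volume_ml(es_label, RV)
    return out


# --------------------------------------------------------------------------
# agreement statistics
# --------------------------------------------------------------------------

@dataclass
class AgreementResult:
    """Bland-Altman summary on the pairs surviving the IQR outlier rule."""

    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    n_used: int
    n_removed: int


def bland_altman(auto_values: Sequence[float], manual_values: Sequence[float],
                 iqr_rule: bool = True) -> AgreementResult:
    """Bland-Altman agreement of paired measurements.

    Per pair, the mean m_i = (a_i + b_i)/2 and difference d_i = a_i - b_i are
    formed; with `iqr_rule` (the default) pairs whose m_i falls outside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of the m distribution are removed before
    computing the mean difference, its sample s.d. and the limits of
    agreement MD +/- 1.96 s.d.
    """
    a = np.asarray(auto_values, dtype=np.float64)
    b = np.asarray(manual_values, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired value lists of equal length required")
    if a.size < 3:
        raise ValidationError(f"need n >= 3 pairs, got {a.size}")
    m = (a + b) / 2.0
    d = a - b
    keep = np.ones(a.size, dtype=bool)
    if iqr_rule:
        q1, q3 = np.percentile(m, [25, 75])  # linear interpolation
        iqr = q3 - q1
        keep = (m >= q1 - 1.5 * iqr) & (m <= q3 + 1.5 * iqr)
    d_used = d[keep]
    md = float(d_used.mean())
    sd = float(d_used.std(ddof=1)) if d_used.size > 1 else 0.0
    return AgreementResult(
        mean_difference=md, sd_difference=sd,
        loa_lower=md - 1.96 * sd, loa_upper=md + 1.96 * sd,
        n_used=int(keep.sum()), n_removed=int((~keep).sum()),
    )


def spearman_r(auto_values: Sequence[float], manual_values: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties) of paired lists."""
    a = np.asarray(auto_values, dtype=np.float64)
    b = np.asarray(manual_values, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValidationError("paired lists with n >= 3 required")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("rank correlation undefined for a constant list")
    return float(stats.spearmanr(a, b).statistic)


# --------------------------------------------------------------------------
# dataset-level evaluation
# --------------------------------------------------------------------------

def evaluate_dataset(
    predictions: Dict[str, Tuple[LabelMap, LabelMap]],
    references: List[SubjectStudy],
    iqr_rule: bool = True,
) -> Dict[str, object]:
    """Score predicted (ED, ES) label maps against reference studies.

    Returns a dict with:
      - 'dice': tidy DataFrame (subject, frame, structure, dice),
      - 'dice_summary': per-structure mean and s.d. pooled over frames/subjects,
      - 'params': per-subject auto/manual clinical parameters,
      - 'agreement': DataFrame (parameter, MD, SD, LOA_low, LOA_high, n_used,
        n_removed, spearman_r), rows only for parameters with >= 3 pairs.

    Structures without reference labels in a frame are skipped, not scored 0.
    """
    ref_by_id = {s.subject_id: s for s in references}
    overlap = [sid for sid in predictions if sid in ref_by_id]
    if not overlap:
        raise ValidationError("no overlapping subjects between predictions and references")

    dice_rows = []
    param_rows = []
    for sid in overlap:
        study = ref_by_id[sid]
        pred_ed, pred_es = predictions[sid]
        for frame, pred in (("ED", pred_ed), ("ES", pred_es)):
            ref = study.ed_label if frame == "ED" else study.es_label
            if ref is None:
                continue
            if pred.shape != ref.shape:
                raise ValidationError(
                    f"{sid} {frame}: prediction grid {pred.shape} != reference {ref.shape}")
            for cls, name in STRUCTURES.items():
                if not study.available(frame, cls):
                    continue
                dice_rows.append({"subject": sid, "frame": frame,
                                  "structure": name,
                                  "dice": dice_3d(pred, ref, cls)})
        avail = lambda frame, cls: study.available(frame, cls)
        auto = clinical_params(pred_ed, pred_es, availability=avail)
        manual = clinical_params(study.ed_label, study.es_label, availability=avail)
        row = {"subject": sid}
        for k in CLINICAL_PARAMS:
            row[f"auto_{k}"] = auto.as_dict()[k]
            row[f"manual_{k}"] = manual.as_dict()[k]
        param_rows.append(row)

    dice_df = pd.DataFrame(dice_rows)
    summary = (dice_df.groupby("structure")["dice"].agg(["mean", "std", "count"])
               if not dice_df.empty else pd.DataFrame())
    params_df = pd.DataFrame(param_rows)

    agreement_rows = []
    for k in CLINICAL_PARAMS:
        sub = params_df[[f"auto_{k}", f"manual_{k}"]].dropna()
        if len(sub) < 3:
            continue
        res = bland_altman(sub[f"auto_{k}"], sub[f"manual_{k}"], iqr_rule=iqr_rule)
        try:
            rho = spearman_r(sub[f"auto_{k}"], sub[f"manual_{k}"])
        except ValidationError:
            rho = np.nan
        agreement_rows.append({
            "parameter": k, "MD": res.mean_difference, "SD": res.sd_difference,
            "LOA_low": res.loa_lower, "LOA_high": res.loa_upper,
            "n_used": res.n_used, "n_removed": res.n_removed, "spearman_r": rho,
        })
    return {
        "dice": dice_df,
        "dice_summary": summary,
        "params": params_df,
        "agreement": pd.DataFrame(agreement_rows),
    }


def mean_foreground_dice(dice_df: pd.DataFrame) -> float:
    """Mean Dice over the three foreground structures, all entries pooled."""
    return float(dice_df["dice"].mean())
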