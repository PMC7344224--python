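"""Augmentation/normalization ablation: train with one operation removed at
a time, evaluate within-domain and cross-domain.

The study design: every row shares one training protocol except that a
single operation — in-plane resampling, rotation, flip, or scale
augmentation — is switched off. All models are evaluated on held-out
subjects from the training domain and on a shifted domain; the expected
pattern is that within-domain scores barely move while cross-domain scores
drop whenever an operation is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .augment import AugmentConfig
from .evaluate import evaluate_dataset, mean_foreground_dice
from .inference import segment_study
from .preprocess import PreprocessConfig
from .train import TrainConfig, train_model
from .types import SubjectStudy
from .unet import UNet, UNetConfig

#: The standard single-toggle rows, named by what is removed.
DEFAULT_ROWS = ("full", "no_resample", "no_rotation", "no_flip", "no_scale")


def row_configs(preprocess: PreprocessConfig, augment: AugmentConfig,
                row: str) -> Tuple[PreprocessConfig, AugmentConfig]:
    """Derive one row's configs from the base pair by removing one operation."""
    if row == "full":
        return preprocess, augment
    if row == "no_resample":
        return replace(preprocess, resample_enabled=False), augment
    if row == "no_rotation":
        return preprocess, replace(augment, rotation_enabled=False)
    if row == "no_flip":
        return preprocess, replace(augment, flip_enabled=False)
    if row == "no_scale":
        return preprocess, replace(augment, scale_enabled=False)
    raise ValueError(f"unknown ablation row {row!r}")


@dataclass
class AblationResult:
    """Per-row scores and the trained models (models optional to keep)."""

    table: pd.DataFrame
    histories: Dict[str, object]


def _evaluate(network: UNet, studies: List[SubjectStudy],
              preprocess: PreprocessConfig) -> Tuple[float, pd.DataFrame]:
    preds = {s.subject_id: segment_study(network, s, preprocess) for s in studies}
    report = evaluate_dataset(preds, studies)
    return mean_foreground_dice(report["dice"]), report["dice_summary"]


def run_ablation(
    train_studies: List[SubjectStudy],
    val_studies: List[SubjectStudy],
    test_in_domain: List[SubjectStudy],
    test_shifted: List[SubjectStudy],
    model_config: UNetConfig,
    train_config: TrainConfig,
    preprocess_config: PreprocessConfig,
    augment_config: Optional[AugmentConfig] = None,
    rows: Sequence[str] = DEFAULT_ROWS,
    log=None,
) -> AblationResult:
    """Train one model per ablation row and score all of them on both test sets.

    Evaluation always uses each row's own preprocessing (a model trained
    without resampling is also tested without it, as its deployment would
    be). Rows that fail to train are marked failed and the grid is still
    returned.
    """
    augment_config = augment_config or AugmentConfig()
    records = []
    histories: Dict[str, object] = {}
    for row in rows:
        try:
            pre, aug = row_configs(preprocess_config, augment_config, row)
            net = UNet(model_config, seed=train_config.seed)
            net, hist = train_model(net, train_studies, val_studies,
                                    train_config, pre, aug, log=log)
            histories[row] = hist
            in_dice, in_table = _evaluate(net, test_in_domain, pre)
            out_dice, out_table = _evaluate(net, test_shifted, pre)
            rec = {"row": row, "failed": False,
                   "in_domain_dice": in_dice, "shifted_dice": out_dice}
            for name, tab in (("in", in_table), ("shifted", out_table)):
                for structure in tab.index:
                    rec[f"{name}_{structure}_mean"] = tab.loc[structure, "mean"]
                    rec[f"{name}_{structure}_sd"] = tab.loc[structure, "std"]
            records.append(rec)
            if log is not None:
                log(f"[{row}] in-domain {in_dice:.3f} shifted {out_dice:.3f}")
        except Exception as exc:  # a failed row must not sink the grid
            records.append({"row": row, "failed": True, "error": str(exc)})
            if log is not None:
                log(f"[{row}] FAILED: {exc}")
    return AblationResult(table=pd.DataFrame(records), histories=histories)
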