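"""Step 2: the multi-ROI network and the Progressive Index.

The MRNet evaluates one shared backbone on the K selected ROI patches of a
subject, concatenates the K feature vectors (FC input K x 64 for the default
backbone) and maps them to 2 logits; the softmax positive-class probability
is the Progressive Index (PI), a continuous score in [0, 1] read as the
propensity to progress. Subjects with unknown follow-up outcome are scored
too — they appear in the PI table and in the overall-mean threshold but never
in sensitivity/specificity counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .nn import (BackboneSpec, MRNetParams, TrainConfig, TrainReport,
                 build_mrnet, forward_probs, predict_proba, train_classifier)
from .screening import ROIRanking, compute_auc, extract_cohort_patches
from .volumes import (LabelVolume, Patch, Volume3D, extract_patch,
                      load_nifti_volume, roi_centroid, standardize_patch)

__all__ = [
    "ThresholdMetrics",
    "subject_patches",
    "train_mrnet",
    "progressive_index",
    "score_cohort",
    "threshold_metrics",
    "stage_sorted_table",
]


@dataclass
class ThresholdMetrics:
    threshold: float
    sensitivity: float
    specificity: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc,
                "counts": {"TP": self.tp, "FP": self.fp,
                           "TN": self.tn, "FN": self.fn}}


def subject_patches(volume: Volume3D, atlas: LabelVolume,
                    selected_rois, size: int = 32,
                    standardize: bool = True) -> list[Patch]:
    """The K centroid patches of one subject, in stored ROI order.

    The order is part of the model contract: the FC head's weights are
    order-sensitive, so patches must always be stacked the way the ranking
    stored them.
    """
    patches = []
    for lid in selected_rois:
        c = roi_centroid(atlas, int(lid))
        p = extract_patch(volume, c, size=size, roi_label=int(lid))
        if standardize:
            p = Patch(data=standardize_patch(p.data), size=size,
                      center=p.center, roi_label=p.roi_label)
        patches.append(p)
    return patches


def _stack(patches: list[Patch]) -> np.ndarray:
    return np.stack([np.asarray(p.data, dtype=np.float32) for p in patches])


def train_mrnet(manifest: pd.DataFrame, atlas: LabelVolume,
                ranking: ROIRanking,
                spec: BackboneSpec | None = None,
                cfg: TrainConfig | None = None,
                patch_size: int = 32,
                standardize: bool = True,
                patches: np.ndarray | None = None
                ) -> tuple[MRNetParams, TrainReport]:
    """Train the K-branch conversion predictor on the labeled subjects.

    ``patches`` may carry pre-extracted patches of shape
    (n_labeled, K, s, s, s) in labeled-row x ranking order to skip image I/O.
    """
    spec = spec or BackboneSpec()
    cfg = cfg or TrainConfig()
    rows = manifest[manifest["label"].notna()].reset_index(drop=True)
    y = rows["label"].astype(int).to_numpy()
    if patches is None:
        patches = extract_cohort_patches(rows, atlas, ranking.selected,
                                         patch_size, standardize=standardize)
    model = build_mrnet(ranking.selected, spec=spec,
                        init_seed=derive_seed(cfg.seed, "mrnet-init"))
    return train_classifier(model, patches, y, cfg)


def progressive_index(model: MRNetParams, patches: list[Patch] | np.ndarray
                      ) -> float:
    """PI of one subject: the positive-class softmax probability in [0, 1]."""
    if isinstance(patches, list):
        labels = [p.roi_label for p in patches]
        if labels and any(l != 0 for l in labels) and \
                tuple(labels) != model.selected_rois:
            raise ValueError(
                f"patch ROI order {labels} != model order "
                f"{list(model.selected_rois)}")
        X = _stack(patches)
    else:
        X = np.asarray(patches, dtype=np.float32)
    if X.shape[0] != model.k:
        raise ValueError(f"model expects {model.k} patches, got {X.shape[0]}")
    return float(forward_probs(model, X[None])[0, 1])


def score_cohort(model: MRNetParams, manifest: pd.DataFrame,
                 atlas: LabelVolume, patch_size: int = 32,
                 standardize: bool = True) -> pd.DataFrame:
    """PI for every manifest subject (unknown-label subjects included).

    Returns the PI table: subject_id, group, label, pi; a subject whose image
    cannot be read gets pi = NaN and an error note instead of aborting the
    cohort run.
    """
    rows = []
    for rec in manifest.itertuples(index=False):
        try:
            vol = load_nifti_volume(rec.image_path)
            pats = subject_patches(vol, atlas, model.selected_rois,
                                   size=patch_size, standardize=standardize)
            pi = progressive_index(model, pats)
            err = ""
        except (OSError, ValueError, KeyError) as e:
            pi, err = float("nan"), str(e)
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     "label": rec.label, "pi": pi, "error": err})
    out = pd.DataFrame(rows)
    out["label"] = pd.array(out["label"], dtype="Int64")
    return out


def threshold_metrics(pi_table: pd.DataFrame,
                      threshold_mode: str | float = "overall_mean"
                      ) -> ThresholdMetrics:
    """Sensitivity/specificity at the overall-average-PI threshold.

    The threshold is the mean PI over ALL scored rows, unknown-label subjects
    included; a subject with PI >= threshold is called positive. The 2x2
    counts and the AUC then use only the rows with a known label.
    """
    ok = pi_table[pi_table["pi"].notna()]
    if threshold_mode == "overall_mean":
        thr = float(ok["pi"].mean())
    else:
        thr = float(threshold_mode)
    known = ok[ok["label"].notna()]
    y = known["label"].astype(int).to_numpy()
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("metrics undefined: need known labels of both classes")
    pi = known["pi"].to_numpy(dtype=float)
    pred = pi >= thr
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    return ThresholdMetrics(
        threshold=thr,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=compute_auc(pi, y),
        tp=tp, fp=fp, tn=tn, fn=fn)


def stage_sorted_table(pi_table: pd.DataFrame,
                       group_order: list[str] | None = None) -> pd.DataFrame:
    """Plot-ready long table (group, index-within-group, pi), stage-sorted.

    Reproduces the structure of a stage plot: subjects grouped by cohort tag,
    ordered within each group by ascending PI.
    """
    ok = pi_table[pi_table["pi"].notna()].copy()
    groups = group_order or sorted(ok["group"].unique())
    parts = []
    for g in groups:
        sub = ok[ok["group"] == g].sort_values("pi").reset_index(drop=True)
        sub["index_in_group"] = np.arange(len(sub))
        parts.append(sub[["group", "index_in_group", "subject_id", "pi"]])
    return pd.concat(parts, ignore_index=True)


def save_metrics_json(metrics: ThresholdMetrics, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(metrics.to_dict(), fh, indent=2)
    return path
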