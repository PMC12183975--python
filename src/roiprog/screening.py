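"""Step 1: per-ROI screening networks and AUC-based region selection.

One single-ROI network (SRNet) is trained per candidate atlas region on the
32^3 (or configured-size) patches at that region's centroid; its held-out
validation AUC measures how well the region alone separates progressive from
stable subjects. Regions are then ranked by AUC and the top K (default 10)
become the input set of the multi-ROI stage.

Each ROI's training seed is derived from the run seed and the label id, so
the screen is reproducible and its result independent of execution order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._seeds import derive_seed
from .nn import BackboneSpec, TrainConfig, build_srnet, train_classifier
from .volumes import (LabelVolume, extract_patch, load_nifti_volume,
                      roi_centroid, standardize_patch)

__all__ = [
    "AUCEntry",
    "AUCTable",
    "ROIRanking",
    "compute_auc",
    "extract_cohort_patches",
    "screen_rois",
    "rank_rois",
]


@dataclass
class AUCEntry:
    label_id: int
    auc: float
    n_train: int
    n_val: int
    seed: int


@dataclass
class AUCTable:
    """Per-ROI screening AUCs."""

    entries: dict[int, AUCEntry] = field(default_factory=dict)

    def to_frame(self, lookup: dict[int, str] | None = None) -> pd.DataFrame:
        rows = [{"label_id": e.label_id,
                 "name": (lookup or {}).get(e.label_id, f"roi_{e.label_id}"),
                 "auc": e.auc, "n_train": e.n_train, "n_val": e.n_val}
                for e in sorted(self.entries.values(), key=lambda e: e.label_id)]
        return pd.DataFrame(rows)

    def save_csv(self, path: str | Path,
                 lookup: dict[int, str] | None = None) -> Path:
        path = Path(path)
        self.to_frame(lookup).to_csv(path, index=False)
        return path


@dataclass
class ROIRanking:
    """Deterministic ordering: descending AUC, ties broken by ascending id."""

    ordered: list[int]
    k: int
    aucs: dict[int, float]

    @property
    def selected(self) -> list[int]:
        return self.ordered[: self.k]

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump({"k": self.k, "ordered": self.ordered,
                       "selected": self.selected,
                       "aucs": {str(k): v for k, v in self.aucs.items()}},
                      fh, indent=2)
        return path

    @classmethod
    def load_json(cls, path: str | Path) -> "ROIRanking":
        with open(path) as fh:
            d = json.load(fh)
        return cls(ordered=[int(i) for i in d["ordered"]], k=int(d["k"]),
                   aucs={int(k): float(v) for k, v in d["aucs"].items()})


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank-sum (Mann-Whitney) formulation.

    The probability that a random positive outranks a random negative, with
    ties credited 0.5. Requires at least one sample of each class.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D sequences")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one sample per class")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5 credit
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def extract_cohort_patches(manifest: pd.DataFrame, atlas: LabelVolume,
                           roi_labels: list[int], patch_size: int,
                           standardize: bool = True) -> np.ndarray:
    """Centroid patches for every subject x ROI in one pass over the images.

    Returns float32 of shape (n_subjects, n_rois, s, s, s) in manifest row
    order and ``roi_labels`` order. Loading each volume once dominates the
    cost of a screen, so all candidate patches are cut together.
    """
    centroids = {lid: roi_centroid(atlas, lid) for lid in roi_labels}
    out = np.empty((len(manifest), len(roi_labels)) + (patch_size,) * 3,
                   dtype=np.float32)
    for i, path in enumerate(manifest["image_path"].tolist()):
        vol = load_nifti_volume(path)
        for j, lid in enumerate(roi_labels):
            patch = extract_patch(vol, centroids[lid], size=patch_size,
                                  roi_label=lid)
            data = standardize_patch(patch.data) if standardize else patch.data
            out[i, j] = data
    return out


def _labeled_rows(manifest: pd.DataFrame) -> pd.DataFrame:
    return manifest[manifest["label"].notna()].reset_index(drop=True)


def screen_rois(manifest: pd.DataFrame, atlas: LabelVolume,
                candidate_labels: list[int] | None = None,
                spec: BackboneSpec | None = None,
                cfg: TrainConfig | None = None,
                patch_size: int = 32,
                standardize: bool = True,
                screen_contrast: str = "composite",
                patches: np.ndarray | None = None) -> AUCTable:
    """Train one SRNet per candidate ROI and record its held-out AUC.

    ``screen_contrast`` chooses the label contrast: ``composite`` uses every
    labeled row (progressive-vs-stable composite), ``ad_vs_nc`` restricts to
    rows whose group tag is AD or a NC variant. ``patches`` may carry
    pre-extracted patches (labeled-row x candidate order) to skip image I/O.
    """
    spec = spec or BackboneSpec()
    cfg = cfg or TrainConfig()
    present = set(atlas.label_ids())
    if candidate_labels is None:
        candidate_labels = sorted(present)
    for lid in candidate_labels:
        if lid not in present:
            raise KeyError(f"candidate label {lid} not present in atlas")

    rows = _labeled_rows(manifest)
    if screen_contrast == "ad_vs_nc":
        keep = rows["group"].map(lambda g: g == "AD" or "NC" in str(g))
        rows = rows[keep].reset_index(drop=True)
    elif screen_contrast != "composite":
        raise ValueError("screen_contrast must be 'composite' or 'ad_vs_nc'")
    y = rows["label"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("screening needs labeled subjects of both classes")

    if patches is None:
        patches = extract_cohort_patches(rows, atlas, list(candidate_labels),
                                         patch_size, standardize=standardize)
    if patches.shape[0] != len(rows) or patches.shape[1] != len(candidate_labels):
        raise ValueError("pre-extracted patch array does not match the cohort")

    table = AUCTable()
    for j, lid in enumerate(candidate_labels):
        roi_seed = derive_seed(cfg.seed, "srnet", lid)
        roi_cfg = TrainConfig(learning_rate=cfg.learning_rate,
                              batch_size=cfg.batch_size, epochs=cfg.epochs,
                              seed=roi_seed,
                              validation_fraction=cfg.validation_fraction)
        model = build_srnet(lid, spec=spec,
                            init_seed=derive_seed(roi_seed, "init"))
        _, report = train_classifier(model, patches[:, j:j + 1], y, roi_cfg)
        table.entries[lid] = AUCEntry(label_id=lid, auc=report.val_auc,
                                     n_train=report.n_train,
                                     n_val=report.n_val, seed=roi_seed)
    return table


def rank_rois(table: AUCTable, k: int = 10) -> ROIRanking:
    """Order ROIs by descending screening AUC and keep the top ``k``."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(table.entries):
        raise ValueError(
            f"k={k} exceeds the {len(table.entries)} screened ROIs")
    ordered = sorted(table.entries,
                     key=lambda lid: (-table.entries[lid].auc, lid))
    return ROIRanking(ordered=ordered, k=k,
                      aucs={lid: table.entries[lid].auc for lid in ordered})
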