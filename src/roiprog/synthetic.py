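"""Phantom atlases and synthetic labeled cohorts with planted ROI signal.

The generator emulates the statistical structure the two-step classifier
assumes: a parcellated volume in which a small subset of regions carries a
class-dependent structural change. "Atrophy" in the progressive class is
modeled as an intensity decrease inside the informative ROIs plus erosion of
their outermost voxels to background — a crude but localized proxy for the
subtle volumetric change a progressive subject shows — with additive Gaussian
noise on top. Background intensity is fixed at 0.2 and ROI tissue at 1.0, so
effect sizes are interpretable on a common scale.

Group tags reuse the cohort vocabulary of longitudinal aging studies
(sNC/pNC/rNC, sSCD/pSCD/rSCD, AD/pMCI/sMCI): the leading ``p`` marks subjects
who progressed (label 1), ``s`` stable (label 0) and ``r`` unknown outcome
(label missing); AD is a positive diagnosis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .volumes import (LabelVolume, Volume3D, extract_patch, roi_centroid,
                      save_label_volume, save_nifti_volume, standardize_patch)

__all__ = [
    "EffectSpec",
    "CohortManifest",
    "PatchCohort",
    "make_phantom_atlas",
    "simulate_subject",
    "simulate_cohort",
    "simulate_patch_cohort",
    "group_label",
    "BACKGROUND_INTENSITY",
    "ROI_INTENSITY",
]

BACKGROUND_INTENSITY = 0.2
ROI_INTENSITY = 1.0


@dataclass
class EffectSpec:
    """Class-dependent signal planted in the informative ROIs.

    intensity_shift: intensity subtracted inside informative ROIs for the
        positive class (signal units on the 0.2/1.0 base scale).
    erosion_fraction: fraction of each informative ROI's voxels, outermost by
        distance from the centroid, reset to background for the positive class.
    noise_sd: SD of i.i.d. additive Gaussian noise applied to every subject.
    """

    informative_labels: frozenset[int] = field(default_factory=frozenset)
    intensity_shift: float = 0.0
    erosion_fraction: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.informative_labels = frozenset(int(l) for l in self.informative_labels)
        if not 0 <= self.erosion_fraction < 1:
            raise ValueError("erosion_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if (self.intensity_shift != 0 or self.erosion_fraction > 0) \
                and not self.informative_labels:
            raise ValueError("a nonzero effect needs informative_labels")


@dataclass
class CohortManifest:
    records: pd.DataFrame  # subject_id, image_path, group, label
    atlas_path: Path
    seed: int
    config_hash: str


def group_label(tag: str):
    """Map a group tag to its training label: p*/AD -> 1, s* -> 0, r* -> NA."""
    if tag == "AD" or tag.startswith("p"):
        return 1
    if tag.startswith("s"):
        return 0
    if tag.startswith("r"):
        return pd.NA
    raise ValueError(f"unrecognized group tag: {tag!r}")


def make_phantom_atlas(shape: tuple[int, int, int], n_rois: int,
                       roi_radius: int = 4, seed: int = 0,
                       max_tries: int = 20000) -> LabelVolume:
    """Random non-overlapping spherical ROIs labeled 1..n_rois.

    Centers are drawn uniformly with a margin of one radius from the border;
    a candidate closer than ``2*roi_radius + 1`` to an accepted center is
    rejected. Deterministic for a fixed seed.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    shape = tuple(int(s) for s in shape)
    r = int(roi_radius)
    if any(s < 2 * r + 1 for s in shape):
        raise ValueError(f"spheres of radius {r} do not fit in shape {shape}")
    rng = np.random.default_rng(seed)
    min_d2 = (2 * r + 1) ** 2
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_rois:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_rois} non-overlapping radius-{r} spheres "
                f"in {shape} after {max_tries} tries")
        tries += 1
        c = np.array([rng.integers(r, s - r) for s in shape])
        if all(((c - p) ** 2).sum() >= min_d2 for p in centers):
            centers.append(c)

    labels = np.zeros(shape, dtype=np.int32)
    off = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(off, off, off, indexing="ij")
    ball = dz**2 + dy**2 + dx**2 <= r**2
    for i, c in enumerate(centers, start=1):
        sl = tuple(slice(cc - r, cc + r + 1) for cc in c)
        labels[sl][ball] = i
    return LabelVolume(labels=labels)


def _erosion_mask(atlas: LabelVolume, label_id: int,
                  fraction: float) -> np.ndarray:
    """Boolean mask of the outermost ``fraction`` of an ROI's voxels.

    Voxels are ordered by Euclidean distance from the ROI centroid-of-mass;
    ties break on flat voxel index for determinism.
    """
    idx = np.nonzero(atlas.labels == label_id)
    n = idx[0].size
    coords = np.stack(idx, axis=1).astype(np.float64)
    center = coords.mean(axis=0)
    d2 = ((coords - center) ** 2).sum(axis=1)
    flat = np.ravel_multi_index(idx, atlas.shape)
    order = np.lexsort((flat, d2))  # ascending distance, stable
    n_erode = int(np.floor(fraction * n))
    mask = np.zeros(atlas.shape, dtype=bool)
    if n_erode > 0:
        keep = order[n - n_erode:]
        mask[tuple(c[keep] for c in idx)] = True
    return mask


def simulate_subject(atlas: LabelVolume, label: int, effect: EffectSpec,
                     seed: int = 0) -> Volume3D:
    """One phantom image: base tissue/background, planted effect, noise.

    Background voxels get intensity 0.2 and ROI voxels 1.0. For a positive
    subject (label 1) the informative ROIs are darkened by ``intensity_shift``
    and their outermost ``erosion_fraction`` of voxels reset to background;
    Gaussian noise of SD ``noise_sd`` is then added everywhere.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    data = np.where(atlas.labels > 0, ROI_INTENSITY, BACKGROUND_INTENSITY)
    data = data.astype(np.float64)
    if label == 1:
        present = set(atlas.label_ids())
        for lid in sorted(effect.informative_labels):
            if lid not in present:
                raise KeyError(f"informative label {lid} not in atlas")
            roi = atlas.labels == lid
            data[roi] -= effect.intensity_shift
            if effect.erosion_fraction > 0:
                data[_erosion_mask(atlas, lid, effect.erosion_fraction)] = \
                    BACKGROUND_INTENSITY
    if effect.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, effect.noise_sd, size=data.shape)
    return Volume3D(data=data)


@dataclass
class PatchCohort:
    """An in-memory cohort reduced to its centroid patch stacks.

    ``patches`` has shape (n_subjects, n_rois, s, s, s) in manifest-row by
    ``roi_labels`` order; column j of a subject is the patch at the centroid
    of ``roi_labels[j]``. Skips image files entirely, for simulation studies
    where only the patches matter.
    """

    atlas: LabelVolume
    manifest: pd.DataFrame
    roi_labels: list[int]
    patches: np.ndarray
    labels: np.ndarray

    def patch_subset(self, selected: list[int]) -> np.ndarray:
        """Patch columns for ``selected`` ROI labels, in that order."""
        cols = [self.roi_labels.index(int(l)) for l in selected]
        return self.patches[:, cols]


def simulate_patch_cohort(shape, n_rois, effect: EffectSpec,
                          n_per_class: int, patch_size: int,
                          seed: int, roi_radius: int = 4,
                          standardize: bool = True,
                          pos_group: str = "pNC",
                          neg_group: str = "sNC") -> PatchCohort:
    """Generate a two-class cohort and return centroid patches directly.

    Same generative process as :func:`simulate_cohort` (per-subject seeds
    derived from the master seed) but kept in memory: each subject's image is
    simulated, its patch at every ROI centroid extracted (and standardized),
    and the image discarded.
    """
    atlas = make_phantom_atlas(shape, n_rois, roi_radius=roi_radius,
                               seed=derive_seed(seed, "atlas"))
    roi_labels = atlas.label_ids()
    centroids = {l: roi_centroid(atlas, l) for l in roi_labels}
    n = 2 * n_per_class
    X = np.empty((n, len(roi_labels)) + (patch_size,) * 3, dtype=np.float32)
    y = np.empty(n, dtype=np.int64)
    rows = []
    i = 0
    for tag, lab in ((neg_group, 0), (pos_group, 1)):
        for s in range(n_per_class):
            sid = f"{tag}_{s:04d}"
            vol = simulate_subject(atlas, lab, effect,
                                   seed=derive_seed(seed, "subject", sid))
            for j, lid in enumerate(roi_labels):
                p = extract_patch(vol, centroids[lid], size=patch_size,
                                  roi_label=lid)
                X[i, j] = standardize_patch(p.data) if standardize else p.data
            y[i] = lab
            rows.append({"subject_id": sid, "image_path": "", "group": tag,
                         "label": lab})
            i += 1
    man = pd.DataFrame(rows)
    man["label"] = pd.array(man["label"], dtype="Int64")
    return PatchCohort(atlas=atlas, manifest=man, roi_labels=roi_labels,
                       patches=X, labels=y)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def simulate_cohort(out_dir: str | Path,
                    shape: tuple[int, int, int],
                    n_rois: int,
                    effect: EffectSpec,
                    n_per_group: dict[str, int],
                    roi_radius: int = 4,
                    seed: int = 0,
                    compress: bool = False) -> CohortManifest:
    """Write a phantom atlas, one image per subject, and the manifest CSV.

    Per-subject seeds are derived from the master seed and the subject id, so
    regeneration with the same master seed is byte-identical and independent
    of generation order. Unknown-outcome groups (r*) get a missing label.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise IOError(f"cannot create output directory {out_dir}: {e}") from e

    atlas = make_phantom_atlas(shape, n_rois, roi_radius=roi_radius,
                               seed=derive_seed(seed, "atlas"))
    ext = ".nii.gz" if compress else ".nii"
    atlas_path = save_label_volume(atlas, out_dir / f"atlas{ext}")

    rows = []
    for tag in sorted(n_per_group):
        lab = group_label(tag)
        for i in range(int(n_per_group[tag])):
            sid = f"{tag}_{i:04d}"
            sim_label = int(lab) if lab is not pd.NA else 0  # unknowns drawn stable
            vol = simulate_subject(atlas, sim_label, effect,
                                   seed=derive_seed(seed, "subject", sid))
            p = save_nifti_volume(vol, out_dir / f"{sid}{ext}")
            rows.append({"subject_id": sid, "image_path": str(p),
                         "group": tag, "label": lab})
    df = pd.DataFrame(rows, columns=["subject_id", "image_path", "group", "label"])
    df["label"] = pd.array(df["label"], dtype="Int64")

    cfg = {"shape": shape, "n_rois": n_rois, "roi_radius": roi_radius,
           "informative_labels": sorted(effect.informative_labels),
           "intensity_shift": effect.intensity_shift,
           "erosion_fraction": effect.erosion_fraction,
           "noise_sd": effect.noise_sd,
           "n_per_group": {k: int(v) for k, v in sorted(n_per_group.items())},
           "seed": int(seed)}
    chash = _config_hash(cfg)
    df.to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "cohort.json", "w") as fh:
        json.dump({"config": cfg, "config_hash": chash}, fh, indent=2)
    return CohortManifest(records=df, atlas_path=atlas_path, seed=int(seed),
                          config_hash=chash)
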