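"""3D volumes, ROI label atlases, centroids and cubic patch extraction.

Images are assumed skull-stripped and spatially normalized upstream, so an
image volume and the ROI label atlas share one voxel grid and centroids are
computed directly in voxel space. Voxel indices are 0-based; a patch of edge
length ``size`` centred at voxel ``c`` covers the half-open window
``[c - size//2, c + ceil(size/2))`` per axis, so an even size (the default 32)
has a well-defined centre voxel. Voxels falling outside the volume are
zero-filled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume3D",
    "LabelVolume",
    "ROIDescriptor",
    "Patch",
    "load_nifti_volume",
    "save_nifti_volume",
    "load_label_volume",
    "save_label_volume",
    "load_aal116_lookup",
    "list_rois",
    "roi_centroid",
    "extract_patch",
    "standardize_patch",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = ("subject_id", "image_path", "group", "label")


@dataclass
class Volume3D:
    """A 3D intensity grid with voxel size metadata (mm)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer ROI parcellation; label 0 is background."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"atlas must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.all(lab == np.round(lab)):
                raise ValueError("atlas labels must be integers")
            self.labels = lab.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def label_ids(self) -> list[int]:
        """Distinct nonzero labels, ascending."""
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


@dataclass
class ROIDescriptor:
    label_id: int
    name: str
    voxel_count: int
    centroid: tuple[int, int, int]


@dataclass
class Patch:
    """A cubic subvolume of edge length ``size`` centred at ``center``."""

    data: np.ndarray
    size: int
    center: tuple[int, int, int]
    roi_label: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != (self.size,) * 3:
            raise ValueError(
                f"patch data shape {self.data.shape} != ({self.size},)*3"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("patch contains non-finite values")


def _voxel_size_from_header(img: nib.Nifti1Image) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    return tuple(float(v) for v in z)


def load_nifti_volume(path: str | Path) -> Volume3D:
    """Read a 3D NIfTI image into a :class:`Volume3D` (intensities unchanged)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D in {path}")
    return Volume3D(data=np.asarray(data, dtype=np.float64),
                    voxel_size=_voxel_size_from_header(img))


def save_nifti_volume(vol: Volume3D, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(vol.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine),
             str(path))
    return path


def load_label_volume(path: str | Path) -> LabelVolume:
    """Read an integer ROI parcellation from NIfTI."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such atlas: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D atlas, got {data.ndim}D in {path}")
    return LabelVolume(labels=np.asarray(np.round(data), dtype=np.int32),
                       voxel_size=_voxel_size_from_header(img))


def save_label_volume(atlas: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(atlas.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), str(path))
    return path


def load_aal116_lookup() -> dict[int, str]:
    """The shipped AAL-116 parcel name table (label_id -> name).

    Ships as documentation of the standard 116-parcel naming (90 cerebral +
    26 cerebellar/vermis regions); the user supplies the actual label volume.
    """
    ref = resources.files("roiprog.data").joinpath("aal116.tsv")
    with ref.open("r") as fh:
        reader = csv.reader(fh, delimiter="\t")
        return {int(row[0]): row[1] for row in reader if row}


def roi_centroid(atlas: LabelVolume, label_id: int) -> tuple[int, int, int]:
    """Voxel-space centroid of one ROI.

    Per-axis arithmetic mean of the voxel indices carrying ``label_id``,
    rounded half-to-even to an integer index.
    """
    idx = np.nonzero(atlas.labels == label_id)
    if idx[0].size == 0:
        raise KeyError(f"label {label_id} not present in atlas")
    mean = [float(ax.mean()) for ax in idx]
    return tuple(int(np.rint(m)) for m in mean)


def list_rois(atlas: LabelVolume,
              lookup: dict[int, str] | None = None) -> list[ROIDescriptor]:
    """One descriptor per distinct nonzero label, ascending by label id."""
    labs = atlas.labels
    ids, counts = np.unique(labs[labs > 0], return_counts=True)
    out = []
    for lid, cnt in zip(ids, counts):
        lid = int(lid)
        name = (lookup or {}).get(lid, f"roi_{lid}")
        out.append(ROIDescriptor(label_id=lid, name=name,
                                 voxel_count=int(cnt),
                                 centroid=roi_centroid(atlas, lid)))
    return out


def extract_patch(volume: Volume3D, center: tuple[int, int, int],
                  size: int = 32, roi_label: int = 0) -> Patch:
    """Extract the cubic window ``[c - size//2, c + ceil(size/2))`` per axis.

    The window may overhang the volume; out-of-bounds voxels are filled with
    0.0 so ROIs near the border still yield a full-size patch.
    """
    if size <= 0:
        raise ValueError(f"patch size must be positive, got {size}")
    center = tuple(int(c) for c in center)
    lo = [c - size // 2 for c in center]
    hi = [l + size for l in lo]
    out = np.zeros((size,) * 3, dtype=np.float64)
    src = []
    dst = []
    for ax in range(3):
        s0 = max(lo[ax], 0)
        s1 = min(hi[ax], volume.shape[ax])
        if s1 <= s0:  # window entirely outside
            return Patch(data=out, size=size, center=center, roi_label=roi_label)
        src.append(slice(s0, s1))
        dst.append(slice(s0 - lo[ax], s1 - lo[ax]))
    out[tuple(dst)] = volume.data[tuple(src)]
    return Patch(data=out, size=size, center=center, roi_label=roi_label)


def standardize_patch(data: np.ndarray) -> np.ndarray:
    """Per-patch z-scoring; a constant patch maps to all zeros."""
    data = np.asarray(data, dtype=np.float64)
    sd = data.std()
    if sd == 0:
        return np.zeros_like(data)
    return (data - data.mean()) / sd


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a subject manifest CSV.

    Columns: subject_id, image_path, group, label; label is 0, 1 or missing
    (unknown follow-up outcome). Returned with label as nullable Int64.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    df["label"] = pd.array(
        [pd.NA if pd.isna(v) else int(v) for v in df["label"]], dtype="Int64"
    )
    bad = df["label"].dropna()
    if not bad.isin([0, 1]).all():
        raise ValueError("manifest labels must be 0, 1 or missing")
    if df["subject_id"].duplicated().any():
        raise ValueError("manifest subject_ids must be unique")
    return df[list(MANIFEST_COLUMNS)]


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
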