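"""NIfTI I/O and BraTS-style case assembly.

A *case* is a directory holding four co-registered MRI modalities
(Flair, T1, T1ce, T2) and, for training data, an integer label volume
marking tumor subregions.  This module reads those files into the
in-memory containers the rest of the pipeline consumes and writes
predicted masks back out.

Only NIfTI-1 (``.nii`` / ``.nii.gz``) is supported on disk.  Arrays are
indexed ``(x, y, z)``, 0-based; axial slices are planes of fixed ``z``.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Fixed channel order for multi-modal volumes.
MODALITIES = ("flair", "t1", "t1ce", "t2")

#: Default filename patterns per modality (BraTS suffix convention).
DEFAULT_PATTERNS = {
    "flair": "*_flair.nii*",
    "t1": "*_t1.nii*",
    "t1ce": "*_t1ce.nii*",
    "t2": "*_t2.nii*",
    "seg": "*seg*.nii*",
}

#: BraTS 2019 label values; some annotation sets use {1, 3, 4} instead.
DEFAULT_LABEL_SET = frozenset({1, 2, 4})
ALT_LABEL_SET = frozenset({1, 3, 4})

#: Tumor-subregion definitions as label unions, keyed by label_set.
#: ET = enhancing tumor, TC = tumor core, WT = whole tumor; WT ⊇ TC ⊇ ET.
REGION_DEFS = {
    DEFAULT_LABEL_SET: {"ET": {4}, "TC": {1, 4}, "WT": {1, 2, 4}},
    ALT_LABEL_SET: {"ET": {4}, "TC": {1, 4}, "WT": {1, 3, 4}},
}


class VolumeError(ValueError):
    """Raised for malformed volumes, masks, or case directories."""


@dataclass
class MultiModalVolume:
    """Four co-registered 3D intensity channels with spatial metadata.

    ``data`` has shape ``(4, X, Y, Z)`` in the fixed order
    Flair, T1, T1ce, T2.  ``spacing`` is the per-axis voxel size in mm
    and ``affine`` the 4x4 voxel-to-world transform shared by all
    channels.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[0] != len(MODALITIES):
            raise VolumeError(
                f"expected (4, X, Y, Z) data, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("volume contains NaN/Inf after loading")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.data[MODALITIES.index(name)]


@dataclass
class SegmentationMask:
    """Integer label volume with a declared label vocabulary.

    ``labels`` shares the spatial shape of its volume; every nonzero
    voxel must carry a value from ``label_set``.  Subregion masks
    (ET/WT/TC) are unions of label masks, nested WT ⊇ TC ⊇ ET.
    """

    labels: np.ndarray
    label_set: frozenset[int] = DEFAULT_LABEL_SET
    region_defs: dict[str, set[int]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = np.rint(self.labels).astype(np.int16)
            if not np.allclose(self.labels, as_int):
                raise VolumeError("mask contains non-integer values")
            self.labels = as_int
        if self.labels.ndim != 3:
            raise VolumeError("mask must be a 3D label volume")
        self.label_set = frozenset(self.label_set)
        present = set(np.unique(self.labels).tolist()) - {0}
        illegal = present - self.label_set
        if illegal:
            raise VolumeError(
                f"mask contains labels {sorted(illegal)} outside "
                f"label_set {sorted(self.label_set)}"
            )
        if self.region_defs is None:
            self.region_defs = {
                k: set(v)
                for k, v in REGION_DEFS.get(
                    self.label_set, REGION_DEFS[DEFAULT_LABEL_SET]
                ).items()
            }

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def region(self, name: str) -> np.ndarray:
        """Boolean mask of a named subregion (union of its labels)."""
        labels = self.region_defs[name]
        return np.isin(self.labels, sorted(labels))


def read_nifti(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Read one NIfTI-1 volume.

    Returns ``(array, affine, spacing)`` where spacing is the voxel
    size in mm from the header.  Rejects non-3D images.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected a 3D image, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine, dtype=np.float64), spacing


def write_nifti(
    data: np.ndarray, affine: np.ndarray, path: str | os.PathLike
) -> None:
    """Write one 3D array as NIfTI-1, preserving dtype."""
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=np.float64))
    nib.save(img, os.fspath(path))


def write_mask(
    mask: SegmentationMask, affine: np.ndarray, path: str | os.PathLike
) -> None:
    """Write a validated mask as an integer-typed NIfTI file."""
    write_nifti(mask.labels.astype(np.int16), affine, path)


def _find_one(case_dir: str, pattern: str) -> str | None:
    hits = sorted(glob.glob(os.path.join(case_dir, pattern)))
    return hits[0] if hits else None


def load_case(
    case_dir: str | os.PathLike,
    patterns: dict[str, str] | None = None,
    label_set: frozenset[int] = DEFAULT_LABEL_SET,
) -> tuple[MultiModalVolume, SegmentationMask | None]:
    """Assemble a BraTS-layout case directory into memory.

    Channels are stacked in the fixed order Flair, T1, T1ce, T2
    regardless of directory listing order; all four must share one
    shape.  The label file is optional.
    """
    case_dir = os.fspath(case_dir)
    pats = dict(DEFAULT_PATTERNS)
    if patterns:
        pats.update(patterns)

    channels, affine, spacing = [], None, None
    for mod in MODALITIES:
        path = _find_one(case_dir, pats[mod])
        if path is None:
            raise FileNotFoundError(
                f"case {case_dir}: no file matching pattern "
                f"{pats[mod]!r} for modality {mod!r}"
            )
        data, aff, sp = read_nifti(path)
        if not np.all(np.isfinite(data)):
            data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
        if affine is None:
            affine, spacing = aff, sp
        elif data.shape != channels[0].shape:
            raise VolumeError(
                f"case {case_dir}: modality {mod!r} shape {data.shape} "
                f"differs from {channels[0].shape}"
            )
        channels.append(np.asarray(data, dtype=np.float64))

    volume = MultiModalVolume(np.stack(channels), spacing, affine)

    mask = None
    seg_path = _find_one(case_dir, pats["seg"])
    if seg_path is not None:
        labels, _, _ = read_nifti(seg_path)
        if labels.shape != volume.shape:
            raise VolumeError(
                f"case {case_dir}: mask shape {labels.shape} differs "
                f"from volume shape {volume.shape}"
            )
        mask = SegmentationMask(labels, label_set=label_set)
    return volume, mask
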