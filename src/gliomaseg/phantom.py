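"""Synthetic multi-modal brain phantoms in the BraTS case layout.

Each phantom is a smooth ellipsoidal "brain" of uniform tissue
intensity carrying a tumor built from three nested ellipsoids —
edema ⊃ core ⊃ enhancing — at a random interior center.  Per-modality
contrast mimics the qualitative BraTS pattern (edema bright on
Flair/T2, enhancing rim bright on T1ce, core dark on T1) and additive
Gaussian noise is applied last.  Geometry is deliberately simple: the
phantoms exercise the pipeline end to end with known ground truth, they
do not model MR physics or lesion texture.

Every case is fully determined by ``(seed, case_index)``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import (
    DEFAULT_LABEL_SET,
    MultiModalVolume,
    SegmentationMask,
    write_nifti,
)

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset"]

# default per-modality intensities for (tissue, edema, core, enhancing);
# background is 0.  Arbitrary units, ordered to mimic BraTS contrasts.
_DEFAULT_INTENSITIES = {
    "flair": (100.0, 180.0, 130.0, 140.0),
    "t1": (100.0, 90.0, 70.0, 120.0),
    "t1ce": (100.0, 100.0, 70.0, 200.0),
    "t2": (100.0, 180.0, 120.0, 140.0),
}


@dataclass
class PhantomConfig:
    """Geometry, contrast, and noise of the synthetic cases.

    ``edema_radius_range`` bounds the outer (WT) semi-axes in voxels;
    the core and enhancing ellipsoids are shrunken copies, so subregion
    nesting holds by construction.  ``noise_sigma`` defaults to 5% of
    the tissue intensity (i.e. of the tissue/tumor contrast scale).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_cases: int = 8
    label_set: frozenset[int] = DEFAULT_LABEL_SET
    edema_radius_range: tuple[float, float] = (10.0, 16.0)
    core_fraction_range: tuple[float, float] = (0.55, 0.7)
    enhancing_fraction_range: tuple[float, float] = (0.5, 0.7)
    intensities: dict = field(
        default_factory=lambda: {k: v for k, v in _DEFAULT_INTENSITIES.items()}
    )
    noise_sigma: float = 5.0
    smooth_sigma: float = 1.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.shape) < 4 * self.edema_radius_range[1] / 2:
            raise ValueError(
                f"shape {self.shape} too small for edema radii "
                f"{self.edema_radius_range}"
            )
        for k, v in self.intensities.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite intensities for {k}")

    @property
    def labels(self) -> tuple[int, int, int]:
        """(edema, core, enhancing) label values.

        {1,2,4}: edema=2, core=1, enhancing=4 (BraTS convention);
        {1,3,4}: edema=3, core=1, enhancing=4.
        """
        ls = sorted(self.label_set)
        if ls == [1, 2, 4]:
            return (2, 1, 4)
        if ls == [1, 3, 4]:
            return (3, 1, 4)
        raise ValueError(f"unsupported label_set {ls}")


def _ellipsoid(
    shape: tuple[int, int, int], center: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    grids = np.ogrid[[slice(0, s) for s in shape]]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def generate_phantom(
    config: PhantomConfig, case_index: int = 0
) -> tuple[MultiModalVolume, SegmentationMask]:
    """One deterministic phantom case: 4-channel volume + label mask."""
    rng = np.random.default_rng([config.seed, case_index])
    shape = np.asarray(config.shape)

    brain_center = shape / 2.0
    brain_radii = 0.44 * shape
    brain = _ellipsoid(config.shape, brain_center, brain_radii)

    lo, hi = config.edema_radius_range
    edema_radii = rng.uniform(lo, hi, size=3)
    core_radii = edema_radii * rng.uniform(*config.core_fraction_range)
    enh_radii = core_radii * rng.uniform(*config.enhancing_fraction_range)
    # keep the whole edema ellipsoid well inside the brain
    margin = edema_radii + 2.0
    center = np.array(
        [
            rng.uniform(c - 0.7 * (r - m), c + 0.7 * (r - m))
            for c, r, m in zip(brain_center, brain_radii, margin)
        ]
    )

    edema = _ellipsoid(config.shape, center, edema_radii) & brain
    core = _ellipsoid(config.shape, center, core_radii) & brain
    enh = _ellipsoid(config.shape, center, enh_radii) & brain

    lab_edema, lab_core, lab_enh = config.labels
    labels = np.zeros(config.shape, dtype=np.int16)
    labels[edema] = lab_edema
    labels[core] = lab_core
    labels[enh] = lab_enh

    channels = []
    from .volume_io import MODALITIES

    for mod in MODALITIES:
        tissue, i_edema, i_core, i_enh = config.intensities[mod]
        img = np.zeros(config.shape, dtype=np.float64)
        img[brain] = tissue
        img[edema] = i_edema
        img[core] = i_core
        img[enh] = i_enh
        if config.smooth_sigma > 0:
            img = ndimage.gaussian_filter(img, config.smooth_sigma)
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, size=config.shape)
        channels.append(img)

    affine = np.diag([*config.spacing, 1.0])
    volume = MultiModalVolume(np.stack(channels), config.spacing, affine)
    mask = SegmentationMask(labels, label_set=config.label_set)
    return volume, mask


def generate_dataset(
    config: PhantomConfig, out_dir: str | os.PathLike
) -> list[str]:
    """Write ``n_cases`` BraTS-layout case directories plus a manifest.

    Each case directory holds four modality NIfTI files and one ``seg``
    file, loadable by :func:`gliomaseg.volume_io.load_case`; the
    manifest records the per-case seeds so the dataset can be
    regenerated identically.
    """
    from .volume_io import MODALITIES

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    case_dirs = []
    manifest = {"seed": config.seed, "shape": list(config.shape), "cases": []}
    for idx in range(config.n_cases):
        name = f"case_{idx:03d}"
        case_dir = os.path.join(out_dir, name)
        os.makedirs(case_dir, exist_ok=True)
        volume, mask = generate_phantom(config, idx)
        for ci, mod in enumerate(MODALITIES):
            write_nifti(
                volume.data[ci],
                volume.affine,
                os.path.join(case_dir, f"{name}_{mod}.nii.gz"),
            )
        write_nifti(
            mask.labels, volume.affine, os.path.join(case_dir, f"{name}_seg.nii.gz")
        )
        manifest["cases"].append({"name": name, "case_index": idx})
        case_dirs.append(case_dir)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return case_dirs
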