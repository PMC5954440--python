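"""Anterior/posterior seed definition and ROI mean extraction.

A hippocampus label is partitioned at a coronal (world-y) plane into an
anterior and a posterior seed.  The partition plane defaults to the uncal
apex, y = -21 mm in MNI space, and a 2-mm slice on each side of the plane is
excluded from both seeds to avoid cross-contamination between them.  The
per-subject seed value is the arithmetic mean of the (modulated) GM image
over the seed mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError
from .morphometry import GMImage

__all__ = [
    "ROIMask",
    "SeedVector",
    "split_mask_coronal",
    "extract_roi_mean",
    "read_label_image",
    "write_mask",
]

UNCAL_APEX_Y_MM = -21.0  # MNI y of the uncal apex: anterior/posterior boundary
DEFAULT_GAP_MM = 2.0  # excluded coronal slice width on each side of the plane


@dataclass
class ROIMask:
    """A boolean voxel set on the cohort grid."""

    voxels: np.ndarray
    affine: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise GeometryError("ROIMask voxels must be a 3D boolean array")
        if self.affine.shape != (4, 4):
            raise GeometryError("ROIMask affine must be 4x4")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def world_y(self) -> np.ndarray:
        """World y coordinate (mm) of every voxel center on the grid."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.voxels.shape[0]),
            np.arange(self.voxels.shape[1]),
            np.arange(self.voxels.shape[2]),
            indexing="ij",
        )
        M, t = self.affine[:3, :3], self.affine[:3, 3]
        return M[1, 0] * ii + M[1, 1] * jj + M[1, 2] * kk + t[1]


@dataclass
class SeedVector:
    """Per-subject mean GM value over one seed mask, in subject-table order."""

    values: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    mask_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("SeedVector values must be 1D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SeedVector values must be finite")
        if self.subject_ids and len(self.subject_ids) != len(self.values):
            raise ValueError("subject_ids length does not match values")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        ids = self.subject_ids or [str(i) for i in range(len(self.values))]
        return pd.DataFrame({"subject_id": ids, "value": self.values})


def _check_same_grid(shape_a, affine_a, shape_b, affine_b, what: str) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise GeometryError(f"{what}: grid shapes differ ({shape_a} vs {shape_b})")
    if not np.allclose(affine_a, affine_b, atol=1e-6):
        raise GeometryError(f"{what}: affines differ")


def split_mask_coronal(
    mask: ROIMask,
    boundary_y_mm: float = UNCAL_APEX_Y_MM,
    gap_mm: float = DEFAULT_GAP_MM,
) -> tuple[ROIMask, ROIMask]:
    """Split a mask at a coronal plane into (anterior, posterior) seeds.

    Voxel membership is decided by the voxel-center world y coordinate:
    anterior voxels satisfy y > boundary + gap, posterior voxels
    y < boundary - gap.  Voxels whose centers fall in the closed band
    [boundary - gap, boundary + gap] belong to neither output, so the two
    seeds plus the removed band exactly tile the input mask.

    Returns empty outputs (with a warning) when the mask does not extend
    past the band on one side.
    """
    if gap_mm < 0:
        raise ValueError(f"gap_mm must be non-negative, got {gap_mm}")
    if mask.n_voxels == 0:
        raise ValueError("cannot split an empty mask")
    y = mask.world_y()
    anterior = mask.voxels & (y > boundary_y_mm + gap_mm)
    posterior = mask.voxels & (y < boundary_y_mm - gap_mm)
    base = mask.name or "mask"
    for side, vox in (("anterior", anterior), ("posterior", posterior)):
        if not vox.any():
            warnings.warn(
                f"{base}: {side} seed is empty — the mask does not extend past "
                f"y = {boundary_y_mm} ± {gap_mm} mm on that side",
                stacklevel=2,
            )
    return (
        ROIMask(voxels=anterior, affine=mask.affine.copy(), name=f"{base}_anterior"),
        ROIMask(voxels=posterior, affine=mask.affine.copy(), name=f"{base}_posterior"),
    )


def extract_roi_mean(images: list[GMImage], mask: ROIMask) -> SeedVector:
    """Mean GM value over the mask for each image, in input order."""
    if mask.n_voxels == 0:
        raise ValueError(f"mask {mask.name!r} is empty: cannot extract a mean")
    if not images:
        raise ValueError("no images given")
    idx = mask.voxels
    values = np.empty(len(images), dtype=np.float64)
    for i, img in enumerate(images):
        _check_same_grid(img.shape, img.affine, idx.shape, mask.affine, "extract_roi_mean")
        values[i] = float(img.data[idx].mean())
    return SeedVector(
        values=values,
        subject_ids=[img.subject_id for img in images],
        mask_name=mask.name,
    )


def read_label_image(path, sidecar=None) -> dict[str, ROIMask]:
    """Read an integer label NIfTI plus an optional JSON label->name sidecar.

    Returns one binary :class:`ROIMask` per label value.  Without a sidecar,
    masks are named ``label_<value>``.
    """
    from .morphometry import read_image

    img = read_image(path)
    labels = np.unique(img.data)
    labels = labels[labels != 0]
    names: dict[int, str] = {}
    if sidecar is not None:
        with open(sidecar) as fh:
            names = {int(v): str(k) for k, v in json.load(fh).items()}
    out: dict[str, ROIMask] = {}
    for lab in labels:
        name = names.get(int(lab), f"label_{int(lab)}")
        out[name] = ROIMask(voxels=img.data == lab, affine=img.affine, name=name)
    return out


def write_mask(mask: ROIMask, path) -> None:
    """Write a binary mask as uint8 NIfTI-1."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine), str(path))
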