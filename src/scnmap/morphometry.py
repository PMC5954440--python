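"""Volumetric image plumbing: the gray-matter image container, NIfTI-1 I/O
and isotropic Gaussian smoothing.

The container holds modulated gray-matter (GM) density-like values on a
regular 3D grid together with a 4x4 voxel-index -> world-mm affine.  Only
axis-aligned grids (diagonal 3x3 affine block) are supported; spatially
normalized VBM output lives on such grids, and resampling rotated data is
out of scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import GeometryError, ImageIOError

__all__ = [
    "GMImage",
    "FWHM_TO_SIGMA",
    "fwhm_to_sigma",
    "smooth_image",
    "read_image",
    "write_image",
]

#: sigma = FWHM * this factor, from FWHM = 2 * sqrt(2 ln 2) * sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a kernel of the given full width at half maximum."""
    return fwhm_mm * FWHM_TO_SIGMA


@dataclass
class GMImage:
    """A 3D gray-matter volume with its voxel-to-world affine.

    Parameters
    ----------
    data
        3D array of GM values (unitless modulated density). Stored as float64.
    affine
        4x4 voxel-index -> world-mm transform (RAS+ convention).
    subject_id
        Identifier of the subject the volume belongs to.
    """

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(
                f"GMImage data must be 3D, got {self.data.ndim} dimensions"
            )
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise GeometryError("image data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_sizes(self) -> np.ndarray:
        """Absolute voxel edge lengths (mm) per axis; requires an axis-aligned grid."""
        return np.abs(np.diag(_require_axis_aligned(self.affine)))

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinates of every voxel center, one 3D array per axis."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        M, t = self.affine[:3, :3], self.affine[:3, 3]
        x = M[0, 0] * ii + M[0, 1] * jj + M[0, 2] * kk + t[0]
        y = M[1, 0] * ii + M[1, 1] * jj + M[1, 2] * kk + t[1]
        z = M[2, 0] * ii + M[2, 1] * jj + M[2, 2] * kk + t[2]
        return x, y, z


def _require_axis_aligned(affine: np.ndarray) -> np.ndarray:
    """Return the 3x3 block of an axis-aligned affine, or raise."""
    rot = np.asarray(affine, dtype=float)[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(rot))):
        raise GeometryError(
            "only axis-aligned grids (diagonal affine) are supported; "
            "resample rotated/sheared data upstream"
        )
    return rot


def smooth_image(img: GMImage, fwhm_mm: float, *, mode: str = "constant") -> GMImage:
    """Convolve an image with an isotropic Gaussian kernel of given FWHM.

    The kernel width is isotropic in *world* millimetres: per axis,
    sigma(voxels) = fwhm_mm * FWHM_TO_SIGMA / voxel_size(axis).

    Parameters
    ----------
    img
        Input volume on an axis-aligned grid.
    fwhm_mm
        Full width at half maximum of the kernel, mm, > 0.
    mode
        Boundary handling: ``"constant"`` (zero padding, default — the
        natural choice for masked brain images) or ``"nearest"``.
    """
    from scipy import ndimage

    if not fwhm_mm > 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    if mode not in ("constant", "nearest"):
        raise ValueError(f"unsupported boundary mode {mode!r}")
    voxel = np.abs(np.diag(_require_axis_aligned(img.affine)))
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel
    out = ndimage.gaussian_filter(
        img.data.astype(np.float64), sigma=sigma_vox, mode=mode, cval=0.0
    )
    return GMImage(data=out, affine=img.affine.copy(), subject_id=img.subject_id)


def read_image(path) -> GMImage:
    """Load a 3D NIfTI-1 volume (.nii or .nii.gz) as a :class:`GMImage`.

    The subject id is taken from the file stem (``sub-01.nii.gz`` -> ``sub-01``).
    """
    try:
        nii = nib.load(str(path))
    except FileNotFoundError:
        raise ImageIOError(f"image file not found: {path}") from None
    except Exception as exc:  # nibabel raises several format errors
        raise ImageIOError(f"could not read {path}: {exc}") from exc
    data = np.asanyarray(nii.dataobj)
    if data.ndim != 3:
        raise ImageIOError(
            f"{path}: expected a 3D volume, got {data.ndim}D data of shape {data.shape}"
        )
    name = str(path).rsplit("/", 1)[-1]
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return GMImage(data=np.asarray(data, dtype=np.float64), affine=nii.affine, subject_id=name)


def write_image(img: GMImage, path, dtype=np.float32) -> None:
    """Write a :class:`GMImage` to NIfTI-1; ``.nii.gz`` paths are compressed.

    Data are cast to ``dtype`` (float32 default; a float32<->float64 round
    trip through :func:`read_image` is exact for float32-representable data,
    pass ``dtype=np.float64`` for full precision).
    """
    nii = nib.Nifti1Image(img.data.astype(dtype), img.affine)
    try:
        nib.save(nii, str(path))
    except Exception as exc:
        raise ImageIOError(f"could not write {path}: {exc}") from exc
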