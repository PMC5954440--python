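"""Synthetic cohort generation with planted covariance and trajectory structure.

The generator emulates a cross-sectional VBM cohort: subjects in up to three
age groups, a latent per-subject hippocampal seed volume following a
quadratic lifespan trajectory (optionally with age-dependent dispersion),
and modulated-GM-like images in which

* hippocampus-label voxels carry the latent seed value itself, so the ROI
  mean over the label recovers it;
* every other voxel is background + group-specific coupling to the seed
  + an additive gender effect + i.i.d. Gaussian noise.

Because the coupling maps, trajectory coefficients and realized latent
values are returned as ground truth, every downstream stage (seed
extraction, trajectory fits, covariance GLM, interaction inference) can be
checked against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .morphometry import GMImage
from .seeds import ROIMask

__all__ = [
    "SubjectRecord",
    "CohortSpec",
    "CohortTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_null_cohort",
    "write_cohort",
]

DEFAULT_AGE_RANGES = ((18, 23), (30, 58), (61, 89))
DEFAULT_GROUP_LABELS = ("young", "middle", "old")
# Table-1-like sex composition: 50/80, 50/80, 55/80 female.
DEFAULT_FEMALE_FRACTION = (0.625, 0.625, 0.6875)


@dataclass
class SubjectRecord:
    """One participant: id, age in years, gender code (female=1), group label."""

    id: str
    age: int
    gender: int
    group: str


@dataclass
class CohortSpec:
    """Generative specification of a synthetic cohort.

    Parameters
    ----------
    n_per_group
        Subjects per age group (>= 4).
    age_ranges
        Inclusive integer age interval per group; one to three groups.
    group_labels
        Group names, matching ``age_ranges`` in length.
    female_fraction
        Fraction of female subjects per group (scalar applies to all groups).
    grid_shape, voxel_size_mm, world_origin_mm
        Image grid: voxel counts per axis (each >= 8), isotropic spacing (mm)
        and the world coordinate of voxel (0,0,0).
    hippo_box
        World-mm box ((x0,x1),(y0,y1),(z0,z1)) defining the hippocampus
        label; must straddle the anterior/posterior partition plane
        (y = -21 mm) by more than the 2-mm exclusion gap on each side.
    traj_coeffs
        (b0, b1, b2): latent seed volume = b0 + b1*age + b2*age² + noise.
    eta_sd
        SD of the latent trajectory noise (constant across age).
    eta_sd_quadratic
        Optional (a0, a1, a2) making the latent SD a quadratic in age,
        SD(t) = max(a0 + a1*t + a2*t², 0); enables U-shaped dispersion.
        Overrides ``eta_sd`` when set.
    coupling_map
        Per-group voxel coupling strengths λ_v: mapping group label -> 3D
        array on the grid (zero outside designated coupled regions). Missing
        groups couple with zero everywhere.
    gender_effect
        Additive per-voxel effect γ_v of gender (scalar or 3D array).
    voxel_noise_sd
        SD of i.i.d. Gaussian voxel noise.
    mu_background
        Background voxel mean μ_v (GM-density-like scale).
    rng_seed
        Integer seed; identical spec + seed reproduces output bit for bit.
    """

    n_per_group: int = 80
    age_ranges: tuple = DEFAULT_AGE_RANGES
    group_labels: tuple = DEFAULT_GROUP_LABELS
    female_fraction: tuple | float = DEFAULT_FEMALE_FRACTION
    grid_shape: tuple = (16, 20, 16)
    voxel_size_mm: float = 2.0
    world_origin_mm: tuple = (-16.0, -40.0, -16.0)
    hippo_box: tuple = ((-10.0, 10.0), (-32.0, -10.0), (-10.0, 10.0))
    traj_coeffs: tuple = (3.5, 0.02, -0.0005)
    eta_sd: float = 0.1
    eta_sd_quadratic: tuple | None = None
    coupling_map: dict = field(default_factory=dict)
    gender_effect: float | np.ndarray = 0.0
    voxel_noise_sd: float = 0.05
    mu_background: float = 0.5
    rng_seed: int = 0

    # anterior/posterior partition plane the hippo box must straddle
    partition_y_mm: float = -21.0
    partition_gap_mm: float = 2.0

    def __post_init__(self) -> None:
        self.group_labels = tuple(self.group_labels)[: len(self.age_ranges)]
        self.validate()

    def validate(self) -> None:
        if self.n_per_group < 4:
            raise ConfigurationError(
                f"n_per_group must be >= 4, got {self.n_per_group}"
            )
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ConfigurationError(
                f"grid_shape must have three axes each >= 8, got {self.grid_shape}"
            )
        if not self.voxel_size_mm > 0:
            raise ConfigurationError(
                f"voxel_size_mm must be positive, got {self.voxel_size_mm}"
            )
        if not (1 <= len(self.age_ranges) <= 3):
            raise ConfigurationError("age_ranges must define one to three groups")
        if len(self.group_labels) != len(self.age_ranges):
            raise ConfigurationError("group_labels must match age_ranges in length")
        for lo, hi in self.age_ranges:
            if hi < lo:
                raise ConfigurationError(f"invalid age range ({lo}, {hi})")
        for frac in np.atleast_1d(np.asarray(self.female_fraction, dtype=float)):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(
                    f"female_fraction must be in [0, 1], got {frac}"
                )
        (_, _), (y0, y1), (_, _) = self.hippo_box
        lo_edge = self.partition_y_mm - self.partition_gap_mm
        hi_edge = self.partition_y_mm + self.partition_gap_mm
        if not (y0 < lo_edge and y1 > hi_edge):
            raise ConfigurationError(
                f"hippo_box y extent ({y0}, {y1}) must straddle the partition "
                f"plane y = {self.partition_y_mm} mm by more than the "
                f"{self.partition_gap_mm} mm exclusion gap on each side"
            )
        for label, lam in self.coupling_map.items():
            if label not in self.group_labels:
                raise ConfigurationError(f"coupling_map has unknown group {label!r}")
            if np.shape(lam) != tuple(self.grid_shape):
                raise ConfigurationError(
                    f"coupling map for {label!r} has shape {np.shape(lam)}, "
                    f"expected {tuple(self.grid_shape)}"
                )
        if np.ndim(self.gender_effect) not in (0, 3):
            raise ConfigurationError("gender_effect must be scalar or a 3D map")
        if np.ndim(self.gender_effect) == 3 and np.shape(self.gender_effect) != tuple(
            self.grid_shape
        ):
            raise ConfigurationError("gender_effect map must match grid_shape")
        if self.voxel_noise_sd < 0 or self.eta_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        aff[:3, 3] = self.world_origin_mm
        return aff

    def female_fraction_for(self, group_index: int) -> float:
        frac = np.atleast_1d(np.asarray(self.female_fraction, dtype=float))
        return float(frac[group_index % len(frac)])

    def latent_sd(self, age) -> np.ndarray:
        """SD of the latent trajectory noise at the given age(s)."""
        age = np.asarray(age, dtype=np.float64)
        if self.eta_sd_quadratic is None:
            return np.full_like(age, self.eta_sd, dtype=np.float64)
        a0, a1, a2 = self.eta_sd_quadratic
        return np.maximum(a0 + a1 * age + a2 * age**2, 0.0)


@dataclass
class CohortTruth:
    """Ground truth realized by the generator."""

    s: np.ndarray  # latent seed volume per subject
    coupling_map: dict  # group label -> λ_v map actually used
    gender_effect: np.ndarray  # γ_v map actually used
    traj_coeffs: tuple


@dataclass
class SyntheticCohort:
    """A generated cohort: subjects, images, hippocampus label, ground truth."""

    subjects: list[SubjectRecord]
    images: list[GMImage]
    hippo_label: ROIMask
    truth: CohortTruth
    spec: CohortSpec

    def subject_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "gender": [s.gender for s in self.subjects],
                "group": [s.group for s in self.subjects],
            }
        )

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects], dtype=np.float64)

    @property
    def genders(self) -> np.ndarray:
        return np.array([s.gender for s in self.subjects], dtype=np.int64)

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])


def _hippo_mask(spec: CohortSpec) -> np.ndarray:
    aff = spec.affine
    idx = [np.arange(n) for n in spec.grid_shape]
    coords = [aff[d, d] * idx[d] + aff[d, 3] for d in range(3)]
    inside = []
    for d, (lo, hi) in enumerate(spec.hippo_box):
        inside.append((coords[d] >= lo) & (coords[d] <= hi))
    mask = (
        inside[0][:, None, None] & inside[1][None, :, None] & inside[2][None, None, :]
    )
    if not mask.any():
        raise ConfigurationError("hippo_box contains no voxel centers on the grid")
    return mask


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort from the spec.

    For subject i with age t: latent seed
    ``s_i = b0 + b1*t + b2*t² + η_i`` with ``η_i ~ N(0, SD(t)²)``.
    Hippocampus-label voxels receive ``s_i`` plus voxel noise (ROI mean over
    the label equals s_i exactly in the noise-free case); every other voxel
    v receives ``μ + λ_v(group_i)·s_i + γ_v·gender_i + ε`` with
    ``ε ~ N(0, voxel_noise_sd²)``.  Ages are uniform integers over the
    group's range; female counts match the group's female fraction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    affine = spec.affine
    hippo = _hippo_mask(spec)
    shape = tuple(spec.grid_shape)

    subjects: list[SubjectRecord] = []
    for g_idx, ((lo, hi), label) in enumerate(zip(spec.age_ranges, spec.group_labels)):
        n = spec.n_per_group
        ages = rng.integers(lo, hi + 1, size=n)
        n_female = int(round(spec.female_fraction_for(g_idx) * n))
        genders = np.zeros(n, dtype=np.int64)
        genders[:n_female] = 1
        genders = rng.permutation(genders)
        for k in range(n):
            subjects.append(
                SubjectRecord(
                    id=f"sub-{len(subjects) + 1:04d}",
                    age=int(ages[k]),
                    gender=int(genders[k]),
                    group=label,
                )
            )

    ages = np.array([s.age for s in subjects], dtype=np.float64)
    b0, b1, b2 = spec.traj_coeffs
    eta = rng.standard_normal(len(subjects)) * spec.latent_sd(ages)
    s = b0 + b1 * ages + b2 * ages**2 + eta

    zero = np.zeros(shape, dtype=np.float64)
    coupling = {
        label: np.asarray(spec.coupling_map.get(label, zero), dtype=np.float64)
        for label in spec.group_labels
    }
    gamma = (
        np.full(shape, float(spec.gender_effect))
        if np.ndim(spec.gender_effect) == 0
        else np.asarray(spec.gender_effect, dtype=np.float64)
    )

    images: list[GMImage] = []
    for i, subj in enumerate(subjects):
        data = spec.mu_background + coupling[subj.group] * s[i] + gamma * subj.gender
        data[hippo] = s[i]
        if spec.voxel_noise_sd > 0:
            data = data + rng.standard_normal(shape) * spec.voxel_noise_sd
        images.append(GMImage(data=data, affine=affine.copy(), subject_id=subj.id))

    return SyntheticCohort(
        subjects=subjects,
        images=images,
        hippo_label=ROIMask(voxels=hippo, affine=affine.copy(), name="hippocampus"),
        truth=CohortTruth(
            s=s,
            coupling_map=coupling,
            gender_effect=gamma,
            traj_coeffs=tuple(spec.traj_coeffs),
        ),
        spec=spec,
    )


def generate_null_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort with no seed coupling or gender effect anywhere.

    The latent seed values are still drawn (so a seed covariate exists) but
    they are independent of every non-label voxel.  A spec carrying nonzero
    coupling or gender-effect maps is rejected: the global null is a
    contract of this generator, not a default to be overridden.
    """
    for label, lam in spec.coupling_map.items():
        if np.any(np.asarray(lam) != 0):
            raise ConfigurationError(
                f"generate_null_cohort requires zero coupling, but group "
                f"{label!r} has a nonzero λ map"
            )
    if np.any(np.asarray(spec.gender_effect) != 0):
        raise ConfigurationError(
            "generate_null_cohort requires a zero gender effect"
        )
    return generate_cohort(spec)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write a cohort to disk: per-subject NIfTI, label image, subjects.csv,
    truth.json (trajectory coefficients + realized latent values)."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for img in cohort.images:
        nib.save(
            nib.Nifti1Image(img.data.astype(np.float32), img.affine),
            str(outdir / f"{img.subject_id}.nii.gz"),
        )
    nib.save(
        nib.Nifti1Image(
            cohort.hippo_label.voxels.astype(np.uint8), cohort.hippo_label.affine
        ),
        str(outdir / "hippocampus_label.nii.gz"),
    )
    with open(outdir / "hippocampus_label.json", "w") as fh:
        json.dump({"hippocampus": 1}, fh)
    cohort.subject_table().to_csv(outdir / "subjects.csv", index=False)
    truth = {
        "rng_seed": cohort.spec.rng_seed,
        "traj_coeffs": list(cohort.truth.traj_coeffs),
        "s": [float(v) for v in cohort.truth.s],
        "subject_ids": [s.id for s in cohort.subjects],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
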