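"""End-to-end validation harnesses on synthetic cohorts.

These routines run the full analysis path (cohort generation, seed
extraction, design construction, voxelwise GLM, permutation thresholds) on
simulated data with known truth, and summarize how the inference behaves:
the empirical family-wise error rate under the global null, and recovery of
a planted group × seed coupling difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortSpec, generate_cohort, generate_null_cohort
from .glm import build_covariance_design, fit_voxelwise_glm, permutation_fwe
from .interaction import build_interaction_design, compare_groups
from .seeds import extract_roi_mean, split_mask_coronal

__all__ = [
    "null_cohort_spec",
    "empirical_height_fwe",
    "planted_interaction_spec",
    "planted_block_recovery",
]


def null_cohort_spec(rng_seed: int, n_subjects: int = 40,
                     grid=(12, 12, 12)) -> CohortSpec:
    """Single-group global-null cohort: i.i.d. Gaussian voxel noise with a
    latent seed volume that is independent of every non-label voxel."""
    return CohortSpec(
        n_per_group=n_subjects,
        age_ranges=((18, 89),),
        group_labels=("all",),
        grid_shape=grid,
        voxel_size_mm=2.0,
        world_origin_mm=(-12.0, -32.0, -12.0),
        hippo_box=((-8.0, 8.0), (-27.0, -15.0), (-8.0, 8.0)),
        rng_seed=rng_seed,
    )


def empirical_height_fwe(
    cohort_seeds,
    n_subjects: int = 40,
    grid=(12, 12, 12),
    n_perm: int = 500,
    alpha: float = 0.05,
    perm_seed_offset: int = 1_000_003,
) -> float:
    """Fraction of null cohorts with any voxel above the height threshold.

    For each seed, draws a global-null cohort, extracts the hippocampal seed
    covariate, fits the covariance GLM over the non-label voxels (the label
    itself carries the latent value by construction, so it is excluded to
    keep the covariate independent of every analysed voxel) and computes
    the max-t permutation height threshold at the nominal level.  Returns
    the empirical family-wise error rate, which should not exceed ``alpha``
    beyond binomial noise.
    """
    hits = 0
    cohort_seeds = list(cohort_seeds)
    for cseed in cohort_seeds:
        cohort = generate_null_cohort(
            null_cohort_spec(int(cseed), n_subjects=n_subjects, grid=grid)
        )
        seed = extract_roi_mean(cohort.images, cohort.hippo_label)
        design = build_covariance_design(seed, cohort.genders)
        mask = ~cohort.hippo_label.voxels
        fit = fit_voxelwise_glm(cohort.images, design, "seed+", mask=mask)
        fwe = permutation_fwe(
            cohort.images, design, "seed+", alpha=alpha, n_perm=n_perm,
            rng_seed=(int(cseed) + perm_seed_offset) % (2**31), mask=mask,
        )
        if np.nanmax(fit.tmap) >= fwe.height_threshold:
            hits += 1
    return hits / len(cohort_seeds)


def planted_interaction_spec(
    rng_seed: int,
    coupling_diff: float = 0.8,
    n_per_group: int = 80,
    grid=(16, 20, 16),
    block=((2, 7), (0, 5), (2, 7)),
) -> CohortSpec:
    """Two-group cohort with a cubic block whose old-group seed coupling
    exceeds the young group's by ``coupling_diff``.

    The default block sits at small y indices, outside the hippocampus
    label (whose voxels carry the latent seed value itself and therefore
    cannot express a planted coupling).
    """
    lam_old = np.zeros(grid)
    (x0, x1), (y0, y1), (z0, z1) = block
    lam_old[x0:x1, y0:y1, z0:z1] = coupling_diff
    return CohortSpec(
        n_per_group=n_per_group,
        age_ranges=((18, 23), (61, 89)),
        group_labels=("young", "old"),
        female_fraction=(0.625, 0.6875),
        grid_shape=grid,
        hippo_box=((-10.0, 10.0), (-31.0, -10.0), (-10.0, 10.0)),
        coupling_map={"old": lam_old},
        rng_seed=rng_seed,
    )


@dataclass
class BlockRecovery:
    """One replicate of planted-block recovery."""

    detected: bool  # a significant young<old cluster overlaps the block
    coupling_estimate: float  # interaction coefficient at the block centroid
    coupling_se: float
    coupling_truth: float


def planted_block_recovery(
    rng_seed: int,
    coupling_diff: float = 0.8,
    n_per_group: int = 80,
    n_perm: int = 500,
    block=((2, 7), (0, 5), (2, 7)),
) -> BlockRecovery:
    """Run the two-group interaction analysis on one planted cohort.

    Detection means some cluster in the young<old table overlaps the planted
    block; the coupling difference estimate is the interaction coefficient
    (and its standard error) at the block's centroid voxel.
    """
    spec = planted_interaction_spec(
        rng_seed, coupling_diff=coupling_diff, n_per_group=n_per_group,
        block=block,
    )
    cohort = generate_cohort(spec)
    anterior, _ = split_mask_coronal(cohort.hippo_label)
    _, lt = compare_groups(
        cohort.images, cohort.subject_table(), anterior,
        group_pair=("young", "old"), n_perm=n_perm,
        rng_seed=(rng_seed + 7_777) % (2**31),
    )
    lam = cohort.truth.coupling_map["old"]
    block_mask = lam != 0
    detected = bool(lt.thresholded is not None
                    and np.any((lt.thresholded != 0) & block_mask))

    # interaction coefficient and SE at the block centroid voxel
    (x0, x1), (y0, y1), (z0, z1) = block
    centroid = ((x0 + x1 - 1) // 2, (y0 + y1 - 1) // 2, (z0 + z1 - 1) // 2)
    seed = extract_roi_mean(cohort.images, anterior)
    g = (cohort.groups == "old").astype(float)
    design = build_interaction_design(seed, g, cohort.genders.astype(float))
    fit = fit_voxelwise_glm(cohort.images, design, "interaction+")
    c = design.contrast("interaction+")
    XtX_inv = np.linalg.inv(design.values.T @ design.values)
    cvar = float(c @ XtX_inv @ c)
    est = float(fit.beta[(4, *centroid)])
    se = float(np.sqrt(fit.sigma2[centroid] * cvar))
    return BlockRecovery(
        detected=detected,
        coupling_estimate=est,
        coupling_se=se,
        coupling_truth=coupling_diff,
    )
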